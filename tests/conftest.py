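"""Shared fixtures: built channel, ground-truth trajectories, WHAM round trips.

Expensive fixtures are session-scoped so the permeation, solvation and
acceptance tests analyse the same synthetic data.
"""

from __future__ import annotations

import numpy as np
import pytest

from cntchan.channel_model import build_channel
from cntchan.atoms import Trajectory
from cntchan.permeation import classify_modes, detect_events
from cntchan.profiles import reference_pmf
from cntchan.synthetic import (KineticParams, UmbrellaProtocol,
                               generate_permeation_trajectory,
                               generate_umbrella_samples, generate_uniform_gas,
                               paper_kcl_02V)
from cntchan.wham import extract_barriers, wham


@pytest.fixture(scope="session")
def channel():
    return build_channel()


@pytest.fixture(scope="session")
def gen_traj():
    """Mixed K+/Na+ trajectory with a generous Na+ fraction for oracles."""
    params = KineticParams(n_events=200, na_fraction=0.1, seed=3)
    traj, truth = generate_permeation_trajectory(params)
    return traj, truth


@pytest.fixture(scope="session")
def gen_events(gen_traj):
    traj, truth = gen_traj
    events = detect_events(traj)
    return traj, truth, events


@pytest.fixture(scope="session")
def paper_mixture_run():
    """The packaged low-field KCl mixture at its study-condition size."""
    traj, truth = generate_permeation_trajectory(paper_kcl_02V(seed=1))
    events = detect_events(traj)
    result = classify_modes(events, traj)
    return traj, truth, result


@pytest.fixture(scope="session")
def wham_roundtrip():
    """Full-protocol umbrella sampling + WHAM for both packaged profiles."""
    out = {}
    for name in ("na_two_site", "k_two_site"):
        ref = reference_pmf(name)
        windows = generate_umbrella_samples(ref, UmbrellaProtocol(seed=11))
        prof = wham(windows)
        bars = extract_barriers(prof)
        m = prof.supported
        ref_e = np.interp(prof.z[m], ref.z, ref.energy)
        resid = prof.energy[m] - ref_e
        rmsd = float(np.sqrt(np.mean((resid - resid.mean()) ** 2)))
        out[name] = {"profile": prof, "barriers": bars, "rmsd": rmsd,
                     "reference": ref}
    return out


def gas_trajectory(n=5000, box=(40.0, 40.0, 40.0), n_frames=1, seed=0,
                   centered=False):
    """Stack independent uniform-gas draws into a trajectory."""
    frames = []
    for f in range(n_frames):
        atoms = generate_uniform_gas(n, box, seed=seed + f)
        pos = atoms.positions - (np.asarray(box) / 2 if centered else 0.0)
        frames.append(pos)
    first = generate_uniform_gas(n, box, seed=seed)
    return Trajectory(np.stack(frames), first.tags, first.elements,
                      0.01 * np.arange(n_frames), np.asarray(box))
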