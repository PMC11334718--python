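"""Pipeline orchestration: build -> simulate -> analyze -> wham.

A run configuration is a plain mapping (usually loaded from YAML) with one
section per stage; :func:`run_pipeline` executes the configured stages in
order and returns a machine-readable summary embedding the seed and a hash
of the configuration, so that re-running the same (config, seed) pair is
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .atoms import Trajectory
from .channel_model import (CarbonylLayout, CNTSpec, assemble_membrane_system,
                            build_channel, ring_spacing)
from .electrostatics import potential_profile
from .io import (events_to_table, flux_to_table, write_charge_table,
                 write_pdb, write_table, write_wham_windows, write_xyz)
from .permeation import (ChannelGeometry, classify_modes, cumulative_flux,
                         detect_events, detect_knock_on, permeation_rate,
                         selectivity_ratio)
from .profiles import reference_pmf
from .solvation import density, locate_profile_peaks
from .synthetic import (KineticParams, UmbrellaProtocol,
                        generate_permeation_trajectory,
                        generate_umbrella_samples)
from .wham import extract_barriers, wham

log = logging.getLogger("cntchan")

DEFAULT_STAGES = ("build", "simulate", "analyze-permeation",
                  "analyze-structure", "potential", "wham")


def demo_config() -> dict:
    """Small, fast demonstration configuration exercising every stage."""
    return {
        "stages": list(DEFAULT_STAGES),
        "generator": {"n_events": 60, "na_fraction": 0.05},
        "umbrella": {"samples_per_window": 1500},
        "seed": 0,
    }


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _filter_kwargs(cls, section: dict) -> dict:
    names = set(getattr(cls, "__dataclass_fields__", {}))
    return {k: v for k, v in section.items() if k in names}


def run_pipeline(config: dict | None = None, seed: int | None = None,
                 outdir=None) -> dict:
    """Execute the configured stages; return the summary dictionary.

    Stage failures abort with the stage name prefixed to the error.
    """
    config = config or {}
    stages = list(config.get("stages", DEFAULT_STAGES))
    if seed is None:
        seed = int(config.get("seed", 0))
    outdir = Path(outdir or config.get("outdir", "cntchan_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"provenance": {
        "seed": seed, "config_hash": config_hash(config),
        "version": __version__, "stages": stages,
    }}
    channel = None
    traj = truth = None
    stage = ""
    try:
        if "build" in stages:
            stage = "build"
            sec = config.get("build", {})
            spec = CNTSpec(**_filter_kwargs(CNTSpec, sec))
            layout = CarbonylLayout(**_filter_kwargs(CarbonylLayout,
                                                     sec.get("layout", {})))
            channel = build_channel(spec, layout, sec.get("charges"))
            write_pdb(channel, outdir / "channel.pdb")
            write_xyz(channel, outdir / "channel.xyz")
            write_charge_table(channel, outdir / "channel_charges.tsv")
            blk = {
                "n_atoms": channel.n_atoms,
                "n_carbonyl_O": int(channel.mask("carbonyl_O").sum()),
                "diameter_nm": round(channel.meta["diameter"] / 10.0, 3),
                "ring_spacing_A": round(ring_spacing(channel), 3),
                "net_charge_e": channel.net_charge(),
            }
            if sec.get("assemble", False):
                system = assemble_membrane_system(
                    channel, tuple(sec.get("box_nm", (5.1, 5.1, 5.1))),
                    sec.get("salts"), seed=seed)
                write_pdb(system.atoms, outdir / "system.pdb")
                blk["system_atoms"] = system.atoms.n_atoms
                blk["min_distance_A"] = system.meta["min_distance"]
            summary["build"] = blk

        if "simulate" in stages:
            stage = "simulate"
            sec = dict(config.get("generator", {}))
            sec.setdefault("seed", seed)
            params = KineticParams(**_filter_kwargs(KineticParams, sec))
            traj, truth = generate_permeation_trajectory(params)
            if config.get("write_trajectory", False):
                write_xyz(traj, outdir / "trajectory.xyz")
            summary["simulate"] = {
                "n_frames": traj.n_frames, "n_events": len(truth),
                "duration_ns": float(traj.times[-1]),
            }

        geom = ChannelGeometry(**_filter_kwargs(ChannelGeometry,
                                                config.get("geometry", {})))
        if "analyze-permeation" in stages and traj is not None:
            stage = "analyze-permeation"
            events = detect_events(traj, geom)
            series = cumulative_flux(events, traj)
            res = classify_modes(events, traj, geom)
            knocks = detect_knock_on(events, traj, geom)
            rk = permeation_rate(series, "ion_K")
            rna = permeation_rate(series, "ion_Na")
            if rna["count"] > 0:
                sr, qual = selectivity_ratio(rk["rate_per_s"],
                                             rna["rate_per_s"])
            else:
                sr, qual = selectivity_ratio(rk["rate_per_s"], 0.0,
                                             count_na=0,
                                             duration_ns=rk["duration_ns"])
            write_table(events_to_table(events), outdir / "events.tsv")
            write_table(flux_to_table(series), outdir / "flux.tsv")
            summary["permeation"] = {
                "n_events": len(events),
                "count_K": rk["count"], "count_Na": rna["count"],
                "rate_K_per_s": rk["rate_per_s"],
                "rate_Na_per_s": rna["rate_per_s"],
                "selectivity_ratio": sr, "sr_qualifier": qual,
                "mode_fractions": res["fractions"],
                "n_knock_on": len(knocks),
            }

        if "analyze-structure" in stages and traj is not None:
            stage = "analyze-structure"
            ax = density(traj, "ion_K", "axial")
            rad_k = density(traj, "ion_K", "radial")
            rad_na = density(traj, "ion_Na", "radial")
            peaks = locate_profile_peaks(ax)
            np.savetxt(outdir / "axial_density_K.tsv",
                       np.column_stack([ax.grid[0], ax.density]),
                       header="z_A density", fmt="%.6g")
            summary["structure"] = {
                "axial_peaks_z": [round(float(p), 2) for p in peaks],
                "n_axial_peaks": len(peaks),
                "radial_peak_K_A": float(rad_k.grid[0][np.argmax(rad_k.density)])
                if rad_k.density.max() > 0 else None,
                "radial_peak_Na_A": float(rad_na.grid[0][np.argmax(rad_na.density)])
                if rad_na.density.max() > 0 else None,
            }

        if "potential" in stages:
            stage = "potential"
            if channel is None:
                raise RuntimeError("potential stage requires the build stage")
            sec = config.get("potential", {})
            prof = potential_profile(channel,
                                     smearing=sec.get("smearing", 1.0),
                                     averaging_radius=sec.get(
                                         "averaging_radius", 0.0))
            np.savetxt(outdir / "potential.tsv",
                       np.column_stack([prof.z, prof.potential]),
                       header=f"z_A phi_{prof.units}", fmt="%.6g")
            imin = int(np.argmin(prof.potential))
            summary["potential"] = {
                "units": prof.units,
                "min_z_A": float(prof.z[imin]),
                "min_value": float(prof.potential[imin]),
            }

        if "wham" in stages:
            stage = "wham"
            sec = config.get("umbrella", {})
            prot = UmbrellaProtocol(**_filter_kwargs(UmbrellaProtocol, sec))
            if "seed" not in sec:
                prot.seed = seed
            blk = {}
            for name in sec.get("profiles", ("na_two_site", "k_two_site")):
                ref = reference_pmf(name)
                windows = generate_umbrella_samples(ref, prot)
                write_wham_windows(windows, outdir / f"umbrella_{name}")
                prof = wham(windows,
                            bin_width=config.get("wham", {}).get("bin_width", 0.1))
                bars = extract_barriers(prof)
                np.savetxt(outdir / f"pmf_{name}.tsv",
                           np.column_stack([prof.z, prof.energy]),
                           header="z_A pmf_kcal_mol", fmt="%.6g")
                blk[name] = {
                    "delta_e1": round(bars.delta_e1, 3),
                    "delta_e2": round(bars.delta_e2, 3)
                    if bars.delta_e2 is not None else None,
                    "converged": prof.converged,
                    "iterations": prof.iterations,
                }
            summary["pmf"] = blk
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
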