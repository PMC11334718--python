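"""Synthetic trajectory, umbrella-window and solvation-snapshot generators.

These generators emulate the statistical structure of atomistic MD of the
biomimetic channel so that every analysis stage can be exercised, with known
ground truth, at desk scale:

* :func:`generate_permeation_trajectory` produces stepwise K+ hopping among
  the four binding sites with knock-on, the two water-spacing permeation
  modes (two intervening waters = mode 1, one = mode 2), and off-axis Na+
  traversals that are knocked on by an incoming K+.  A ground-truth event
  log is returned alongside the trajectory.
* :func:`generate_umbrella_samples` draws Metropolis samples from
  exp(-(U(z) + bias)/kT) for a ladder of harmonic windows, mirroring the
  umbrella-sampling protocol (0.5 Å window spacing, 20 kcal/mol/Å^2 spring).
* :func:`generate_solvation_snapshot` and :func:`generate_uniform_gas`
  build solvation-shell and ideal-gas fixtures for the structural operators.

Water in trajectories is represented by tracer oxygens only: the mode
classifier needs only the count of waters between consecutive in-channel
cations.  Full 3-site water appears in solvation snapshots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .atoms import AtomSet, Trajectory
from .profiles import ReferencePMF, reference_pmf
from .units import kT
from .wham import UmbrellaWindow

__all__ = [
    "KineticParams", "GroundTruthEvent", "UmbrellaProtocol",
    "generate_permeation_trajectory", "generate_umbrella_samples",
    "generate_solvation_snapshot", "generate_uniform_gas",
    "paper_kcl_02V",
]

# idealised channel geometry used by the generator (Å): the 13.34 Å section
# with four carbonyl-layer sites spaced 2.7 Å about the centre
CHANNEL_HALF_LENGTH = 6.67
DEFAULT_SITE_Z = (4.05, 1.35, -1.35, -4.05)   # S1..S4, top to bottom
INLET_Z, OUTLET_Z = -6.3, 6.3
SITE_LABELS = ("S1", "S2", "S3", "S4")


@dataclass
class KineticParams:
    """Kinetic and geometric parameters of the event generator.

    Defaults encode the mixed-solution, low-field study conditions: mode 1
    carries 76% of K+ events and Na+ traversals are rare (one per 2000
    events), entering off-axis and leaving only when knocked on.
    """

    site_z: tuple = DEFAULT_SITE_Z
    hop_rate: float = 8.0          # per ns; mean site dwell = 1/hop_rate
    mode1_prob: float = 0.76
    na_fraction: float = 1.0 / 2000.0
    na_radial_offset: float = 2.0  # Å off-axis for Na+
    k_radial_offset: float = 0.3   # Å off-axis for K+
    n_events: int = 100
    frame_dt: float = 0.01         # ns
    seed: int = 0
    transit_time: float = 0.03     # ns between stations
    approach_time: float = 0.15    # ns bulk -> inlet
    mouth_dwell: float = 0.08      # ns mean pause at inlet/outlet
    tail_time: float = 0.1         # ns of idle frames at the end
    reference_pmf: ReferencePMF | None = None
    temperature: float = 300.0

    def __post_init__(self):
        if not (0 <= self.mode1_prob <= 1 and 0 <= self.na_fraction <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.hop_rate <= 0 or self.frame_dt <= 0:
            raise ValueError("rates and timestep must be positive")
        if not all(a > b for a, b in zip(self.site_z, self.site_z[1:])):
            raise ValueError("site_z must be strictly decreasing (S1 top)")


@dataclass
class GroundTruthEvent:
    """One generated traversal: what the analysis should recover."""

    species: str                     # "ion_K" | "ion_Na"
    atom_index: int
    entry_frame: int
    exit_frame: int
    mode: str | None                 # "mode1" | "mode2" | None (Na+)
    site_path: list[str] = field(default_factory=list)
    site_dwell_frames: list[tuple[str, int]] = field(default_factory=list)
    knocked_on_by: str | None = None


def paper_kcl_02V(n_events: int = 2000, seed: int = 0) -> KineticParams:
    """Packaged mixture configuration for the low-field KCl+NaCl condition."""
    return KineticParams(n_events=n_events, seed=seed)


class _Track:
    """Piecewise-linear waypoint track for one particle."""

    def __init__(self, pos):
        self.t = [0.0]
        self.p = [np.asarray(pos, dtype=float)]

    def hold(self, t):
        if t > self.t[-1]:
            self.t.append(float(t))
            self.p.append(self.p[-1])

    def goto(self, t0, t1, pos):
        """Stay put until t0, then move linearly to ``pos`` by t1."""
        self.hold(t0)
        self.t.append(float(max(t1, t0 + 1e-9)))
        self.p.append(np.asarray(pos, dtype=float))

    def jump(self, t, pos):
        self.hold(t)
        self.goto(t, t + 1e-9, pos)

    def sample(self, times):
        t = np.array(self.t)
        p = np.stack(self.p)
        return np.column_stack([np.interp(times, t, p[:, k]) for k in range(3)])


def generate_permeation_trajectory(params: KineticParams | None = None
                                   ) -> tuple[Trajectory, list[GroundTruthEvent]]:
    """Stepwise-hopping ion trajectory with ground-truth event log.

    Events are laid out sequentially.  A K+ event approaches from the lower
    reservoir, pauses at the inlet, then dwells at S4 while a partner K+
    from the upper reservoir transiently occupies S1 with the mode's water
    tracers (two for mode 1, one for mode 2) spaced between the two cations;
    the partner then returns to the upper bulk (it never crosses the
    entrance, so it is not a permeation event) and the event ion hops
    S4->S3->S2->S1 with exponential dwells and exits.  A Na+ event enters
    off-axis to S3 and advances to the exit only after an incoming K+
    arrives at S4 behind it (knock-on); the knocker retreats without
    permeating.  Dwell means are 1/hop_rate, optionally Boltzmann-weighted
    by a reference profile evaluated at the site positions.
    """
    p = params if params is not None else KineticParams()
    rng = np.random.default_rng(p.seed)
    dt = p.frame_dt
    tr = p.transit_time
    s1, s2, s3, s4 = p.site_z

    # site dwell means, optionally Boltzmann-weighted by a reference profile
    base = 1.0 / p.hop_rate
    if p.reference_pmf is not None:
        u = np.asarray(p.reference_pmf(np.array(p.site_z)), dtype=float)
        w = np.exp(-(u - u.mean()) / kT(p.temperature))
        w /= np.exp(np.log(w).mean())
        site_tau = dict(zip(SITE_LABELS, base * w))
    else:
        site_tau = dict.fromkeys(SITE_LABELS, base)

    kx = p.k_radial_offset
    nx = p.na_radial_offset
    PARK_KA = np.array([kx, 0.0, -15.0])
    PARK_KB = np.array([0.3, 0.3, 15.0])
    PARK_NA_BOT = np.array([nx, 0.0, -16.0])
    PARK_NA_TOP = np.array([nx, 0.0, 16.0])
    W_PARKS = [np.array([0.0, 1.0, 14.5]), np.array([0.0, -1.0, 14.8])]
    W_MODE1 = [np.array([0.3, 0.0, -1.35]), np.array([-0.3, 0.0, 1.35])]
    W_MODE2 = [np.array([0.3, 0.0, 0.0])]

    ka, kb = _Track(PARK_KA), _Track(PARK_KB)
    na = _Track(PARK_NA_BOT)
    ws = [_Track(W_PARKS[0]), _Track(W_PARKS[1])]
    tags = np.array(["ion_K", "ion_K", "ion_Na", "water_O", "water_O"],
                    dtype=object)

    def dwell(mean):
        return float(np.clip(rng.exponential(mean), 2 * dt, 8 * mean))

    events: list[GroundTruthEvent] = []
    t = 0.05
    is_na = rng.random(p.n_events) < p.na_fraction
    is_mode1 = rng.random(p.n_events) < p.mode1_prob

    def frame_of(time):
        return int(math.floor(time / dt))

    for ev in range(p.n_events):
        if not is_na[ev]:
            mode = "mode1" if is_mode1[ev] else "mode2"
            waters = W_MODE1 if mode == "mode1" else W_MODE2
            ka.jump(t, [kx, 0.0, -12.0])
            ka.goto(t, t + p.approach_time, [kx, 0.0, INLET_Z])
            for wtrack, wpos in zip(ws, waters):
                wtrack.goto(t, t + p.approach_time, wpos)
            kb.goto(t, t + p.approach_time, [0.3, 0.3, 8.0])
            t1 = t + p.approach_time
            entry_t = t + p.approach_time * (12.0 + -CHANNEL_HALF_LENGTH) / (12.0 + INLET_Z)
            d_in = 0.02 + dwell(p.mouth_dwell)
            kb.goto(t1, t1 + min(0.05, d_in), [0.3, 0.3, s1])
            dwells = [("inlet", t1, d_in)]
            t2 = t1 + d_in
            ka.goto(t2, t2 + tr, [kx, 0.0, s4])
            d_s4 = dwell(site_tau["S4"])
            dwells.append(("S4", t2 + tr, d_s4))
            t3 = t2 + tr + d_s4
            # partner and waters return to the upper bulk (knock-on picture)
            kb.goto(t3, t3 + 0.08, [0.3, 0.3, 8.0])
            kb.jump(t3 + 0.08, PARK_KB)
            for wtrack, park in zip(ws, W_PARKS):
                wtrack.goto(t3, t3 + 0.08, park)
            tcur = t3
            for label, z in (("S3", s3), ("S2", s2), ("S1", s1)):
                ka.goto(tcur, tcur + tr, [kx, 0.0, z])
                d = dwell(site_tau[label])
                dwells.append((label, tcur + tr, d))
                tcur += tr + d
            d_out = 0.02 + dwell(p.mouth_dwell)
            ka.goto(tcur, tcur + tr, [kx, 0.0, OUTLET_Z])
            dwells.append(("outlet", tcur + tr, d_out))
            tcur += tr + d_out
            ka.goto(tcur, tcur + 0.08, [kx, 0.0, 12.0])
            exit_t = tcur + 0.08 * (CHANNEL_HALF_LENGTH + 2.0 - OUTLET_Z) / (12.0 - OUTLET_Z)
            tcur += 0.08
            ka.jump(tcur, PARK_KA)
            events.append(GroundTruthEvent(
                species="ion_K", atom_index=0,
                entry_frame=frame_of(entry_t) + 1,
                exit_frame=frame_of(exit_t) + 1,
                mode=mode,
                site_path=["S4", "S3", "S2", "S1"],
                site_dwell_frames=[(lab, frame_of(ts + 0.5 * d))
                                   for lab, ts, d in dwells
                                   if lab in SITE_LABELS],
            ))
            t = tcur + 0.02
        else:
            na.jump(t, [nx, 0.0, -12.0])
            na.goto(t, t + p.approach_time, [nx, 0.0, INLET_Z])
            entry_t = t + p.approach_time * (12.0 + -CHANNEL_HALF_LENGTH) / (12.0 + INLET_Z)
            t1 = t + p.approach_time
            d_in = 0.02 + dwell(p.mouth_dwell)
            t_s4 = t1 + d_in
            na.goto(t_s4, t_s4 + tr, [nx, 0.0, s4])       # arrive S4
            t_s3 = t_s4 + tr + 0.05                        # brief S4 pause
            na.goto(t_s3, t_s3 + tr, [nx, 0.0, s3])        # hop on to S3
            d_s3 = dwell(1.0 / p.hop_rate) + 0.1
            dwell_mid = [("S3", frame_of(t_s3 + tr + 0.5 * d_s3))]
            t3 = t_s3 + tr + d_s3
            # incoming K+ arrives at S4 behind the bound Na+
            ka.jump(t3 - 0.1, [kx, 0.0, -12.0])
            ka.goto(t3 - 0.1, t3, [kx, 0.0, s4])
            t4 = t3 + 0.02
            tcur = t4
            for label, z in (("S2", s2), ("S1", s1)):
                na.goto(tcur, tcur + tr, [nx, 0.0, z])
                tcur += tr + 0.02
            na.goto(tcur, tcur + tr, [nx, 0.0, OUTLET_Z])
            tcur += tr + 0.02
            na.goto(tcur, tcur + 0.08, [nx, 0.0, 12.0])
            exit_t = tcur + 0.08 * (CHANNEL_HALF_LENGTH + 2.0 - OUTLET_Z) / (12.0 - OUTLET_Z)
            tcur += 0.08
            na.jump(tcur, PARK_NA_TOP)
            # knocker retreats to the lower bulk: no K+ event
            ka.goto(tcur, tcur + 0.1, [kx, 0.0, -12.0])
            ka.jump(tcur + 0.1, PARK_KA)
            na.jump(tcur + 0.1, PARK_NA_BOT)
            events.append(GroundTruthEvent(
                species="ion_Na", atom_index=2,
                entry_frame=frame_of(entry_t) + 1,
                exit_frame=frame_of(exit_t) + 1,
                mode=None,
                site_path=["S4", "S3", "S2", "S1"],
                site_dwell_frames=dwell_mid,
                knocked_on_by="ion_K",
            ))
            t = tcur + 0.12

    t_end = t + p.tail_time
    for track in (ka, kb, na, *ws):
        track.hold(t_end)
    n_frames = max(int(t_end / dt), 10)
    times = dt * np.arange(n_frames)
    pos = np.empty((n_frames, 5, 3))
    for i, track in enumerate((ka, kb, na, *ws)):
        pos[:, i, :] = track.sample(times)
    elements = np.array(["K", "K", "Na", "O", "O"], dtype=object)
    traj = Trajectory(pos, tags, elements, times,
                      meta={"frame_dt": dt, "generator": "permeation",
                            "seed": p.seed, "n_events": p.n_events})
    return traj, events


@dataclass
class UmbrellaProtocol:
    """Umbrella-sampling window ladder (harmonic bias along z)."""

    center_min: float = -10.0
    center_max: float = 10.0
    center_step: float = 0.5
    spring_k: float = 20.0         # kcal/mol/Å^2
    samples_per_window: int = 10_000
    temperature: float = 300.0
    seed: int = 0
    proposal_scale: float = 1.5    # Metropolis step, units of bias sigma
    thin: int = 8                  # chain steps per kept sample

    def __post_init__(self):
        if self.center_min >= self.center_max:
            raise ValueError("center_min must be < center_max")
        if self.spring_k <= 0:
            raise ValueError("spring_k must be > 0")

    @property
    def centers(self) -> np.ndarray:
        return np.arange(self.center_min,
                         self.center_max + self.center_step / 2,
                         self.center_step)


def generate_umbrella_samples(pmf: ReferencePMF | str,
                              protocol: UmbrellaProtocol | None = None
                              ) -> list[UmbrellaWindow]:
    """Metropolis-sample each window's biased density exp(-(U+w_i)/kT).

    The first half of every chain is discarded as burn-in (mirroring the
    equilibration half of each umbrella window); the kept half has exactly
    ``samples_per_window`` entries.  All windows are advanced in lockstep as
    independent vectorised chains.
    """
    if isinstance(pmf, str):
        pmf = reference_pmf(pmf)
    prot = protocol if protocol is not None else UmbrellaProtocol()
    lo, hi = pmf.z_range
    if prot.center_min < lo or prot.center_max > hi:
        raise ValueError("reference profile range narrower than the window ladder")
    rng = np.random.default_rng(prot.seed)
    centers = prot.centers
    kT_ = kT(prot.temperature)
    k = prot.spring_k
    n_keep = prot.samples_per_window
    n_prod = prot.thin * n_keep
    n_steps = 2 * n_prod           # first half of each chain is burn-in
    step = prot.proposal_scale * math.sqrt(kT_ / k)

    z = centers.copy()
    e = pmf(z) + 0.5 * k * (z - centers) ** 2
    kept = np.empty((len(centers), n_keep))
    for i in range(n_steps):
        z_new = z + rng.normal(0.0, step, size=len(centers))
        e_new = pmf(z_new) + 0.5 * k * (z_new - centers) ** 2
        accept = np.log(rng.random(len(centers))) < (e - e_new) / kT_
        z = np.where(accept, z_new, z)
        e = np.where(accept, e_new, e)
        prod_i = i - n_prod
        if prod_i >= 0 and (prod_i + 1) % prot.thin == 0:
            kept[:, prod_i // prot.thin] = z
    return [UmbrellaWindow(center=float(c), spring_k=k, samples=kept[j].copy())
            for j, c in enumerate(centers)]


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _water_sites(o_pos, dipole):
    """3-site rigid water at ``o_pos`` with its dipole along ``dipole``."""
    d = _unit(dipole)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    perp = _unit(np.cross(d, ref))
    half = math.radians(104.52 / 2)
    oh = 0.9572
    h1 = o_pos + oh * (math.cos(half) * d + math.sin(half) * perp)
    h2 = o_pos + oh * (math.cos(half) * d - math.sin(half) * perp)
    return h1, h2


def generate_solvation_snapshot(ion: str = "K", n_water: int = 6,
                                n_carbonyl: int = 0,
                                radii: dict | None = None,
                                seed: int = 0,
                                dipole_axis=None) -> AtomSet:
    """Ion at the origin with shell waters (3-site) and carbonyl oxygens.

    ``radii`` maps partner kinds to placement distances in Å
    (default water_O at 2.8, carbonyl_O at 2.7).  Water dipoles point along
    ``dipole_axis`` if given, otherwise away from the ion.
    """
    if n_water < 0 or n_carbonyl < 0:
        raise ValueError("counts must be >= 0")
    radii = {"water_O": 2.8, "carbonyl_O": 2.7, **(radii or {})}
    rng = np.random.default_rng(seed)
    tag = {"K": "ion_K", "Na": "ion_Na"}[ion]
    positions = [np.zeros(3)]
    tags = [tag]
    charges = [1.0]

    def sphere_points(n, r, min_dist=2.2):
        """Uniform points on the sphere with a steric minimum separation."""
        pts: list[np.ndarray] = []
        tries = 0
        while len(pts) < n:
            v = rng.normal(size=3)
            p = r * v / np.linalg.norm(v)
            if all(np.linalg.norm(p - q) >= min_dist for q in pts) or \
                    tries > 2000:
                pts.append(p)
            tries += 1
        return np.array(pts).reshape(n, 3)

    for o in sphere_points(n_water, radii["water_O"]):
        dip = _unit(dipole_axis) if dipole_axis is not None else _unit(o)
        h1, h2 = _water_sites(o, dip)
        positions += [o, h1, h2]
        tags += ["water_O", "water_H", "water_H"]
        charges += [-0.834, 0.417, 0.417]
    for c in sphere_points(n_carbonyl, radii["carbonyl_O"]):
        positions.append(c)
        tags.append("carbonyl_O")
        charges.append(-0.51)
    out = AtomSet.from_tags(tags, np.array(positions))
    out.charges = np.array(charges)
    return out


def generate_uniform_gas(n: int, box=(40.0, 40.0, 40.0), seed: int = 0,
                         tag: str = "water_O") -> AtomSet:
    """n points i.i.d. uniform in an orthorhombic box (ideal-gas fixture)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    pos = rng.uniform(0.0, 1.0, size=(n, 3)) * box
    out = AtomSet.from_tags([tag] * n, pos.reshape(-1, 3))
    out.meta["box"] = tuple(box)
    return out
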