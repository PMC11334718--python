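"""Ion permeation analysis: traversal detection, fluxes, selectivity,
site occupancy, water-spacing permeation modes and knock-on annotation.

A permeation event is a maximal passage of an ion from below the entrance
plane (minus a committed-entry buffer) to above the exit plane (plus the
buffer) in the +z direction; an ion must return below the entrance buffer
before it can start a new event, so each traversal is counted once and
partial excursions are discarded.

K+ traversals are classified by the number of water molecules spaced
between the ion and the next cation above it inside the channel: two
intervening waters define mode 1 (the knock-on-like pathway), one water
defines mode 2.  The event label is the modal count over the frames where
such a cation pair exists.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import linregress

from .atoms import Trajectory

__all__ = [
    "ChannelGeometry", "EventRecord", "FluxSeries",
    "detect_events", "cumulative_flux", "permeation_rate",
    "selectivity_ratio", "assign_sites", "classify_modes", "detect_knock_on",
    "KnockOnAnnotation",
]

NS_TO_S = 1e-9


@dataclass
class ChannelGeometry:
    """Crossing planes, committed-entry buffer and binding-site positions."""

    entrance_z: float = -6.67
    exit_z: float = 6.67
    buffer: float = 2.0
    site_z: tuple = (4.05, 1.35, -1.35, -4.05)   # S1..S4 top to bottom
    site_tolerance: float = 1.35                  # half the layer spacing

    def __post_init__(self):
        if self.entrance_z >= self.exit_z:
            raise ValueError("entrance_z must be below exit_z")
        for z in self.site_z:
            if not (self.entrance_z < z < self.exit_z):
                raise ValueError("site_z must lie inside the channel")

    @property
    def site_labels(self) -> tuple:
        return tuple(f"S{i + 1}" for i in range(len(self.site_z)))


@dataclass
class EventRecord:
    """One completed ion traversal."""

    species: str
    atom_index: int
    entry_frame: int
    exit_frame: int
    site_path: list[str] = field(default_factory=list)
    mode: str = "unclassified"
    radial_mean: float = float("nan")

    def __post_init__(self):
        if self.entry_frame >= self.exit_frame:
            raise ValueError("entry_frame must precede exit_frame")


@dataclass
class FluxSeries:
    """Cumulative permeation counts per species on the frame time grid."""

    time: np.ndarray                       # ns
    counts: dict                           # species tag -> cumulative array
    field_strength: float | None = None    # V/nm, metadata

    def final_count(self, species: str) -> int:
        c = self.counts.get(species)
        return int(c[-1]) if c is not None and len(c) else 0


def detect_events(traj: Trajectory, geom: ChannelGeometry | None = None
                  ) -> list[EventRecord]:
    """Detect completed +z traversals of every cation in the trajectory."""
    if geom is None:
        geom = ChannelGeometry()
    ion_idx = traj.atom_indices("ion_K", "ion_Na")
    if ion_idx.size == 0:
        raise ValueError("trajectory carries no tagged ion species")
    lo = geom.entrance_z - geom.buffer
    hi = geom.exit_z + geom.buffer
    events: list[EventRecord] = []
    occupancy = assign_sites(traj, geom)
    for ai in ion_idx:
        z = traj.positions[:, ai, 2]
        armed = z[0] < lo
        entry = None
        for f in range(traj.n_frames):
            if z[f] < lo:
                armed = True
                entry = None
                continue
            if not armed:
                continue
            if entry is None and z[f] >= geom.entrance_z:
                entry = f
            if z[f] > hi:
                if entry is None:
                    entry = f
                inside = slice(entry, f + 1)
                path_codes = occupancy[inside, np.nonzero(ion_idx == ai)[0][0]]
                path = [geom.site_labels[c] for c in _dedupe(path_codes)
                        if c >= 0]
                in_ch = (z[inside] >= geom.entrance_z) & (z[inside] <= geom.exit_z)
                xy = traj.positions[inside, ai, :2][in_ch]
                radial = float(np.hypot(xy[:, 0], xy[:, 1]).mean()) if len(xy) else float("nan")
                events.append(EventRecord(
                    species=str(traj.tags[ai]), atom_index=int(ai),
                    entry_frame=int(entry), exit_frame=int(f),
                    site_path=path, radial_mean=radial))
                armed = False
                entry = None
    events.sort(key=lambda e: e.exit_frame)
    return events


def _dedupe(codes):
    out = []
    for c in codes:
        if not out or out[-1] != c:
            out.append(int(c))
    return out


def cumulative_flux(events: list[EventRecord], traj_or_time,
                    field_strength: float | None = None) -> FluxSeries:
    """Step function of cumulative traversals per species vs time (ns)."""
    if isinstance(traj_or_time, Trajectory):
        time = traj_or_time.times
    else:
        time = np.asarray(traj_or_time, dtype=float)
        if time.ndim == 0:
            if float(time) <= 0:
                raise ValueError("total_time must be > 0")
            time = np.linspace(0.0, float(time), 1001)
    species = sorted({e.species for e in events} | {"ion_K", "ion_Na"})
    counts = {}
    for sp in species:
        exits = np.sort([time[min(e.exit_frame, len(time) - 1)]
                         for e in events if e.species == sp])
        counts[sp] = np.searchsorted(exits, time, side="right").astype(int)
    return FluxSeries(time=time, counts=counts, field_strength=field_strength)


def permeation_rate(series: FluxSeries, species: str = "ion_K") -> dict:
    """Permeation rate in ions per second.

    The headline rate is the least-squares slope of the cumulative count vs
    time (the slope of the flux staircase); count/duration is reported
    alongside.
    """
    t = series.time
    if len(t) < 2 or t[-1] <= t[0]:
        raise ValueError("zero-duration flux series")
    c = series.counts.get(species, np.zeros_like(t))
    duration_ns = float(t[-1] - t[0])
    n = int(c[-1])
    slope = 0.0
    if n > 0:
        slope = float(linregress(t, c).slope)
    return {"rate_per_s": slope / NS_TO_S,
            "count_rate_per_s": n / (duration_ns * NS_TO_S),
            "count": n, "duration_ns": duration_ns}


def selectivity_ratio(rate_k: float, rate_na: float,
                      count_na: int | None = None,
                      duration_ns: float | None = None) -> tuple[float, str]:
    """K+/Na+ selectivity ratio with a lower-bound qualifier when Na+ = 0.

    With no observed Na+ events the true rate is only bounded; one
    pseudo-event over the observation time is substituted and the ratio is
    flagged ``lower_bound`` (the microsecond-scale observation of a single
    Na+ traversal motivates this convention).
    """
    if rate_k < 0 or rate_na < 0:
        raise ValueError("rates must be >= 0")
    if count_na == 0 or rate_na == 0:
        if not duration_ns:
            raise ValueError("need duration_ns for the zero-count lower bound")
        pseudo = 1.0 / (duration_ns * NS_TO_S)
        if rate_k == 0:
            raise ValueError("selectivity undefined: both rates are zero")
        return rate_k / pseudo, "lower_bound"
    return rate_k / rate_na, "measured"


def assign_sites(traj: Trajectory, geom: ChannelGeometry | None = None
                 ) -> np.ndarray:
    """Per-frame site occupancy for every cation.

    Returns an integer array (n_frames, n_cations): site index (0 = S1 ...)
    if the ion is within ``site_tolerance`` of a site plane, -1 for
    in-channel but inter-site positions, -2 for outside the channel.
    Cation columns follow ``traj.atom_indices('ion_K', 'ion_Na')`` order.
    """
    if geom is None:
        geom = ChannelGeometry()
    ion_idx = traj.atom_indices("ion_K", "ion_Na")
    z = traj.positions[:, ion_idx, 2]
    sites = np.asarray(geom.site_z)
    d = np.abs(z[:, :, None] - sites[None, None, :])
    nearest = d.argmin(axis=2)
    near_ok = d.min(axis=2) <= geom.site_tolerance
    out = np.where(near_ok, nearest, -1)
    inside = (z >= geom.entrance_z) & (z <= geom.exit_z)
    return np.where(inside, out, -2)


def classify_modes(events: list[EventRecord], traj: Trajectory,
                   geom: ChannelGeometry | None = None) -> dict:
    """Label K+ events mode 1 / mode 2 by intervening-water count.

    For every frame of a K+ event in which the ion is inside the channel
    and another cation sits above it (also in-channel), the water tracers
    with z strictly between the pair are counted; the event's label is the
    modal count (2 -> mode1, 1 -> mode2, anything else unclassified).
    Returns the labelled events plus mode fractions over classified events.
    """
    if geom is None:
        geom = ChannelGeometry()
    w_idx = traj.atom_indices("water_O")
    if w_idx.size == 0:
        raise ValueError("no water tracers in trajectory")
    cat_idx = traj.atom_indices("ion_K", "ion_Na")
    zw = traj.positions[:, w_idx, 2]
    zc = traj.positions[:, cat_idx, 2]
    lo, hi = geom.entrance_z, geom.exit_z
    for ev in events:
        if ev.species != "ion_K":
            ev.mode = "unclassified"
            continue
        counts = []
        for f in range(ev.entry_frame, ev.exit_frame + 1):
            zi = traj.positions[f, ev.atom_index, 2]
            if not (lo <= zi <= hi):
                continue
            above = zc[f][(cat_idx != ev.atom_index) & (zc[f] > zi)
                          & (zc[f] <= hi)]
            if above.size == 0:
                continue
            z_top = above.min()
            counts.append(int(np.sum((zw[f] > zi) & (zw[f] < z_top))))
        if not counts:
            ev.mode = "unclassified"
            continue
        modal = Counter(counts).most_common(1)[0][0]
        ev.mode = {2: "mode1", 1: "mode2"}.get(modal, "unclassified")
    k_events = [e for e in events if e.species == "ion_K"]
    n1 = sum(e.mode == "mode1" for e in k_events)
    n2 = sum(e.mode == "mode2" for e in k_events)
    classified = n1 + n2
    fractions = {"mode1": n1 / classified if classified else float("nan"),
                 "mode2": n2 / classified if classified else float("nan")}
    return {"events": events, "fractions": fractions,
            "n_classified": classified,
            "n_unclassified": len(k_events) - classified}


@dataclass
class KnockOnAnnotation:
    """A bound-ion advance triggered by an incoming cation behind it."""

    atom_index: int
    species: str
    frame: int
    from_site: str
    to_site: str
    partner_index: int
    partner_species: str


def detect_knock_on(events: list[EventRecord], traj: Trajectory,
                    geom: ChannelGeometry | None = None,
                    window_frames: int = 20,
                    approach_cutoff: float = 6.0) -> list[KnockOnAnnotation]:
    """Annotate site advances caused by an incoming cation.

    A transition of a bound ion to a higher site (or out of the channel
    top) is annotated as knock-on when another cation sits within
    ``approach_cutoff`` Å below it at the transition (or arrived there
    within the last ``window_frames`` frames), having been farther away
    before that window.
    """
    if geom is None:
        geom = ChannelGeometry()
    ion_idx = traj.atom_indices("ion_K", "ion_Na")
    occ = assign_sites(traj, geom)
    z = traj.positions[:, ion_idx, 2]
    sites = np.asarray(geom.site_z)
    labels = geom.site_labels
    annotations: list[KnockOnAnnotation] = []
    for col, ai in enumerate(ion_idx):
        s = occ[:, col]
        for f in range(1, traj.n_frames):
            prev, cur = s[f - 1], s[f]
            if prev < 0:
                continue
            advanced = (cur >= 0 and sites[cur] > sites[prev]) or \
                       (cur < 0 and z[f, col] > sites[prev])
            if not advanced:
                continue
            f0 = max(f - window_frames, 0)
            for col2, aj in enumerate(ion_idx):
                if aj == ai:
                    continue
                gap = z[f0:f + 1, col] - z[f0:f + 1, col2]
                near = (gap > 0) & (gap <= approach_cutoff)
                if not near.any():
                    continue
                g0 = max(f0 - 1, 0)
                was_far = not (0 < z[g0, col] - z[g0, col2] <= approach_cutoff)
                if was_far:
                    to_label = labels[cur] if cur >= 0 else "above"
                    annotations.append(KnockOnAnnotation(
                        atom_index=int(ai), species=str(traj.tags[ai]),
                        frame=int(f), from_site=labels[prev],
                        to_site=to_label, partner_index=int(aj),
                        partner_species=str(traj.tags[aj])))
                    break
    return annotations
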