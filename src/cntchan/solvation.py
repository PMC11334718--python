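"""Solvation structure: RDFs, coordination and hydration statistics,
water-dipole orientation and spatial densities.

The first hydration shell is defined by species-specific radii (3.6 Å for
K+, 3.2 Å for Na+, from the bulk RDF first minima); coordination numbers
count oxygen ligands inside the shell, decomposed into water oxygens and
carbonyl oxygens.  RDFs in the confined channel are normalised against a
partner density measured in a user-chosen bulk region, so in-channel
curves are shape-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial import cKDTree

from .atoms import Trajectory

__all__ = [
    "ShellSpec", "RDFResult", "CoordinationProfile", "DensityResult",
    "rdf", "coordination_profile", "hydration_histogram",
    "orientation_histogram", "density", "locate_profile_peaks",
]


@dataclass
class ShellSpec:
    """First-shell radii per ion species and the ligand groups counted."""

    shell_radius: dict = field(default_factory=lambda: {"ion_K": 3.6,
                                                        "ion_Na": 3.2})
    partner_groups: tuple = ("water_O", "carbonyl_O")

    def __post_init__(self):
        if any(r <= 0 for r in self.shell_radius.values()):
            raise ValueError("shell radii must be > 0")


@dataclass
class RDFResult:
    r: np.ndarray
    g: dict                       # group tag -> g(r); plus "total"
    bulk_density: float           # Å^-3 used for normalisation
    first_peak: float
    first_min: float


@dataclass
class CoordinationProfile:
    z: np.ndarray
    total: dict                   # species -> mean coordination per z bin
    carbonyl: dict
    water: dict
    counts: dict                  # species -> samples per z bin


@dataclass
class DensityResult:
    mode: str                     # axial | radial | planar
    grid: tuple                   # bin centres (1 or 2 arrays)
    density: np.ndarray
    bin_measure: np.ndarray       # volume (or length) element per bin
    mean_count: float             # mean in-domain particles per frame


def _pair_distances(centers, partners, r_max, box=None, same_set=False):
    """Directed center->partner distances within r_max (min-image if box)."""
    if len(centers) == 0 or len(partners) == 0:
        return np.empty(0)
    if box is not None:
        box = np.asarray(box, dtype=float)
        tree = cKDTree(np.mod(partners, box), boxsize=box)
        pairs = tree.query_ball_point(np.mod(centers, box), r_max)
        d = []
        for i, nbrs in enumerate(pairs):
            if not nbrs:
                continue
            diff = partners[nbrs] - centers[i]
            diff -= box * np.round(diff / box)
            d.append(np.linalg.norm(diff, axis=1))
        dist = np.concatenate(d) if d else np.empty(0)
    else:
        tree = cKDTree(partners)
        pairs = tree.query_ball_point(centers, r_max)
        d = []
        for i, nbrs in enumerate(pairs):
            if nbrs:
                d.append(np.linalg.norm(partners[nbrs] - centers[i], axis=1))
        dist = np.concatenate(d) if d else np.empty(0)
    if same_set:
        dist = dist[dist > 1e-9]   # drop self pairs
    return dist


def _smooth3(y):
    if len(y) < 3:
        return y
    out = y.copy()
    out[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    return out


def rdf(traj: Trajectory, center_species: str, partner_groups=("water_O",),
        r_max: float = 10.0, dr: float = 0.1, bulk_region=None,
        bulk_density: float | None = None) -> RDFResult:
    """Radial distribution function decomposed by partner group.

    ``bulk_region`` is a (z_lo, z_hi) slab in which the partner number
    density is measured for normalisation (requires a box); alternatively
    pass ``bulk_density`` directly.  Without either, the whole box is used.
    The first minimum is the first local minimum after the global peak of
    the 3-point-smoothed total curve (ties toward smaller r).
    """
    if dr <= 0:
        raise ValueError("dr must be > 0")
    if not partner_groups:
        raise ValueError("empty partner set")
    c_idx = traj.atom_indices(center_species)
    edges = np.arange(0.0, r_max + dr / 2, dr)
    r = 0.5 * (edges[:-1] + edges[1:])
    hists = {g: np.zeros(len(r)) for g in partner_groups}
    n_part_bulk = {g: 0.0 for g in partner_groups}
    for f in range(traj.n_frames):
        centers = traj.positions[f, c_idx]
        for g in partner_groups:
            p_idx = traj.atom_indices(g)
            partners = traj.positions[f, p_idx]
            same = g == center_species
            d = _pair_distances(centers, partners, r_max, traj.box, same)
            hists[g] += np.histogram(d, bins=edges)[0]
            if bulk_region is not None:
                zlo, zhi = bulk_region
                n_part_bulk[g] += np.sum((partners[:, 2] >= zlo)
                                         & (partners[:, 2] <= zhi))
            else:
                n_part_bulk[g] += len(partners)

    if bulk_density is None:
        if traj.box is None:
            raise ValueError("bulk normalisation needs a box or bulk_density")
        lx, ly, lz = traj.box
        if bulk_region is not None:
            vol = lx * ly * (bulk_region[1] - bulk_region[0])
        else:
            vol = lx * ly * lz
        n_total = sum(n_part_bulk.values()) / traj.n_frames
        bulk_density = n_total / vol

    shell_vol = 4.0 * np.pi * r ** 2 * dr
    norm = max(len(c_idx), 1) * traj.n_frames * shell_vol * bulk_density
    g_curves = {g: hists[g] / norm for g in partner_groups}
    g_curves["total"] = np.sum([g_curves[g] for g in partner_groups], axis=0)

    sm = _smooth3(g_curves["total"])
    peak_i = int(np.argmax(sm))
    min_i = peak_i
    for k in range(peak_i + 1, len(sm) - 1):
        if sm[k] < sm[k - 1] and sm[k] <= sm[k + 1]:
            min_i = k
            break
    else:
        min_i = len(sm) - 1
    return RDFResult(r=r, g=g_curves, bulk_density=float(bulk_density),
                     first_peak=float(r[peak_i]), first_min=float(r[min_i]))


def _shell_counts(traj, shells, species, frame):
    """Per-ion (water, carbonyl) neighbour counts in one frame."""
    ion_idx = traj.atom_indices(species)
    radius = shells.shell_radius[species]
    out = []
    pos = traj.positions[frame]
    group_pos = {g: pos[traj.atom_indices(g)] for g in shells.partner_groups}
    trees = {g: cKDTree(p) if len(p) else None for g, p in group_pos.items()}
    for ai in ion_idx:
        counts = {}
        for g, tree in trees.items():
            counts[g] = len(tree.query_ball_point(pos[ai], radius)) if tree else 0
        out.append((float(pos[ai, 2]), counts))
    return out


def coordination_profile(traj: Trajectory, shells: ShellSpec | None = None,
                         z_bins: np.ndarray | None = None,
                         species=("ion_K", "ion_Na")) -> CoordinationProfile:
    """Mean coordination number vs axial position, split by ligand group."""
    if shells is None:
        shells = ShellSpec()
    if z_bins is None:
        z_bins = np.arange(-12.0, 12.01, 0.5)
    centers = 0.5 * (z_bins[:-1] + z_bins[1:])
    nb = len(centers)
    total, carb, wat, nsamp = {}, {}, {}, {}
    for sp in species:
        if sp not in shells.shell_radius:
            continue
        sums = np.zeros((3, nb))
        cnt = np.zeros(nb)
        for f in range(traj.n_frames):
            for z, c in _shell_counts(traj, shells, sp, f):
                b = np.searchsorted(z_bins, z) - 1
                if 0 <= b < nb:
                    w = c.get("water_O", 0)
                    co = c.get("carbonyl_O", 0)
                    sums[:, b] += (w + co, co, w)
                    cnt[b] += 1
        with np.errstate(invalid="ignore"):
            total[sp] = np.where(cnt > 0, sums[0] / cnt, np.nan)
            carb[sp] = np.where(cnt > 0, sums[1] / cnt, np.nan)
            wat[sp] = np.where(cnt > 0, sums[2] / cnt, np.nan)
        nsamp[sp] = cnt
    return CoordinationProfile(z=centers, total=total, carbonyl=carb,
                               water=wat, counts=nsamp)


def hydration_histogram(traj: Trajectory, shells: ShellSpec | None = None,
                        species: str = "ion_K") -> dict:
    """Normalised distribution of the water-only coordination number."""
    if shells is None:
        shells = ShellSpec()
    if traj.atom_indices("water_O").size == 0:
        raise ValueError("no water present")
    counts = []
    for f in range(traj.n_frames):
        for _, c in _shell_counts(traj, shells, species, f):
            counts.append(c.get("water_O", 0))
    if not counts:
        return {}
    values, freq = np.unique(counts, return_counts=True)
    p = freq / freq.sum()
    return {int(v): float(pi) for v, pi in zip(values, p)}


def orientation_histogram(traj: Trajectory, shells: ShellSpec | None = None,
                          reference_axis=(0.0, 0.0, 1.0),
                          species: str = "ion_K",
                          n_bins: int = 18) -> dict:
    """Water-dipole orientation distribution inside the first shell.

    The angle is between the water dipole (from O through the H-H
    midpoint) and ``reference_axis`` (the field direction by default).
    Returns bin centres (deg), the normalised histogram, and the isotropic
    sin(theta) baseline.
    """
    if shells is None:
        shells = ShellSpec()
    o_idx = traj.atom_indices("water_O")
    h_idx = traj.atom_indices("water_H")
    if h_idx.size == 0:
        raise ValueError("orientation analysis needs water hydrogens")
    axis = np.asarray(reference_axis, dtype=float)
    axis /= np.linalg.norm(axis)
    # rigid waters: pair each O with its two nearest H once (frame 0)
    tree = cKDTree(traj.positions[0, h_idx])
    _, nn = tree.query(traj.positions[0, o_idx], k=2)
    ion_idx = traj.atom_indices(species)
    radius = shells.shell_radius[species]
    angles = []
    for f in range(traj.n_frames):
        pos = traj.positions[f]
        o_pos = pos[o_idx]
        in_shell = np.zeros(len(o_idx), bool)
        for ai in ion_idx:
            in_shell |= np.linalg.norm(o_pos - pos[ai], axis=1) <= radius
        for k in np.nonzero(in_shell)[0]:
            h_mid = pos[h_idx[nn[k]]].mean(axis=0)
            dip = h_mid - o_pos[k]
            cosang = np.clip(dip @ axis / np.linalg.norm(dip), -1.0, 1.0)
            angles.append(np.degrees(np.arccos(cosang)))
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    hist = np.histogram(angles, bins=edges)[0].astype(float)
    p = hist / hist.sum() if hist.sum() else hist
    centers = 0.5 * (edges[:-1] + edges[1:])
    baseline = np.sin(np.radians(centers))
    baseline /= baseline.sum()
    return {"theta_deg": centers, "p": p, "isotropic": baseline,
            "n_samples": int(hist.sum())}


def density(traj: Trajectory, species: str, mode: str = "axial",
            bins: np.ndarray | None = None, dr: float = 0.25,
            z_range: tuple = (-6.67, 6.67), r_max: float = 5.0,
            xy_extent: float = 5.0, dxy: float = 0.25) -> DensityResult:
    """Axial, radial or planar particle density, count-normalised.

    axial: counts per z bin per frame / bin length (per Å; per Å^3 if the
    trajectory has a box).  radial: counts per annulus / (2 pi r dr dz)
    over in-channel frames.  planar: x-y map over in-channel frames.
    The density integrates to the mean in-domain particle count per frame.
    """
    idx = traj.atom_indices(species)
    pos = traj.positions[:, idx, :].reshape(-1, 3)
    nf = traj.n_frames
    if mode == "axial":
        if bins is None:
            bins = np.arange(-12.0, 12.01, 0.4)
        centers = 0.5 * (bins[:-1] + bins[1:])
        counts = np.histogram(pos[:, 2], bins=bins)[0] / nf
        measure = np.diff(bins)
        if traj.box is not None:
            measure = measure * traj.box[0] * traj.box[1]
        return DensityResult("axial", (centers,), counts / measure, measure,
                             float(counts.sum()))
    if mode == "radial":
        sel = (pos[:, 2] >= z_range[0]) & (pos[:, 2] <= z_range[1])
        rad = np.hypot(pos[sel, 0], pos[sel, 1])
        edges = np.arange(0.0, r_max + dr / 2, dr)
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = np.histogram(rad, bins=edges)[0] / nf
        measure = 2.0 * np.pi * centers * dr * (z_range[1] - z_range[0])
        return DensityResult("radial", (centers,), counts / measure, measure,
                             float(counts.sum()))
    if mode == "planar":
        sel = (pos[:, 2] >= z_range[0]) & (pos[:, 2] <= z_range[1])
        edges = np.arange(-xy_extent, xy_extent + dxy / 2, dxy)
        h = np.histogram2d(pos[sel, 0], pos[sel, 1], bins=(edges, edges))[0] / nf
        centers = 0.5 * (edges[:-1] + edges[1:])
        measure = np.full(h.shape, dxy * dxy * (z_range[1] - z_range[0]))
        return DensityResult("planar", (centers, centers), h / measure,
                             measure, float(h.sum()))
    raise ValueError(f"unknown density mode {mode!r}")


def locate_profile_peaks(result: DensityResult, prominence_frac: float = 0.05
                         ) -> np.ndarray:
    """Positions of local maxima of a 1-D density profile.

    Default setting: peaks with prominence at least ``prominence_frac`` of
    the profile maximum.
    """
    if result.mode not in ("axial", "radial"):
        raise ValueError("peak location applies to 1-D profiles")
    y = result.density
    pk, _ = find_peaks(y, prominence=prominence_frac * y.max())
    return result.grid[0][pk]
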