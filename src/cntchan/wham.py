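"""Weighted histogram analysis method (WHAM) for 1-D umbrella sampling.

Reconstructs the potential of mean force F(z) from a ladder of harmonically
biased windows by self-consistent iteration of

    P(z) = sum_i n_i(z) / sum_j N_j exp[(F_j - w_j(z)) / kT]
    F_j  = -kT ln sum_z P(z) exp(-w_j(z) / kT)

with w_i(z) = (k_i/2)(z - z_i)^2, until the window free energies F_j are
stationary.  The PMF, -kT ln P(z), is shifted to zero over the bulk
reference (the 2 Å nearest the entrance-side boundary of the supported
range).  Barrier extraction locates stationary points of the smoothed
profile and reports the entrance barrier ΔE1 (first maximum above the bulk
level) and the first-binding-site barrier ΔE2 (second maximum above the
intervening well), followed by any remaining inter-site and exit barriers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .units import kT

__all__ = ["UmbrellaWindow", "PMFProfile", "BarrierSet", "wham",
           "extract_barriers"]


@dataclass
class UmbrellaWindow:
    """One umbrella window: bias centre (Å), spring (kcal/mol/Å^2), samples."""

    center: float
    spring_k: float
    samples: np.ndarray
    n_effective: int | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.spring_k <= 0:
            raise ValueError("spring_k must be > 0")
        if self.samples.size == 0:
            raise ValueError("empty umbrella window")

    def bias(self, z):
        return 0.5 * self.spring_k * (np.asarray(z) - self.center) ** 2


@dataclass
class PMFProfile:
    """Free-energy curve on a uniform z grid; NaN on unsupported bins."""

    z: np.ndarray
    energy: np.ndarray                # kcal/mol, zeroed at the bulk reference
    window_free_energies: np.ndarray
    converged: bool
    iterations: int
    meta: dict = field(default_factory=dict)

    @property
    def supported(self) -> np.ndarray:
        return np.isfinite(self.energy)


@dataclass
class BarrierSet:
    """Ordered barrier heights extracted from a PMF (kcal/mol)."""

    delta_e1: float
    delta_e2: float | None
    inter_site: list[float]
    exit_barrier: float | None
    peaks_z: list[float]
    wells_z: list[float]
    bulk_level: float


def wham(windows: list[UmbrellaWindow], bin_width: float = 0.1,
         temperature: float = 300.0, tol: float = 1e-6,
         max_iter: int = 100_000, z_range: tuple | None = None,
         reference_side: str = "low") -> PMFProfile:
    """Self-consistent WHAM solution over the given windows.

    ``tol`` is the convergence threshold on the largest change of any
    window free energy per iteration, in kcal/mol.  Bins never visited by
    any window are returned as NaN; a gap in the supported range (window
    ladders that do not overlap) is flagged via ``converged=False``.
    """
    if not windows:
        raise ValueError("no umbrella windows")
    kT_ = kT(temperature)
    if z_range is None:
        # robust support: per-window quantiles, so a lone outlier sample
        # cannot open spuriously empty interior bins
        z_lo = min(np.quantile(w.samples, 0.001) for w in windows)
        z_hi = max(np.quantile(w.samples, 0.999) for w in windows)
    else:
        z_lo, z_hi = z_range
    n_bins = max(int(np.ceil((z_hi - z_lo) / bin_width)), 1)
    edges = z_lo + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.stack([np.histogram(w.samples, bins=edges)[0]
                       for w in windows]).astype(float)
    n_tot = counts.sum(axis=0)
    n_samples = np.array([w.n_effective or len(w.samples) for w in windows],
                         dtype=float)
    log_b = np.stack([-w.bias(centers) / kT_ for w in windows])

    f = np.zeros(len(windows))
    converged = False
    it = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        for it in range(1, max_iter + 1):
            # log denominator: log sum_j N_j exp((f_j - w_j)/kT)
            a = np.log(n_samples)[:, None] + f[:, None] / kT_ + log_b
            a_max = a.max(axis=0)
            log_den = a_max + np.log(np.exp(a - a_max).sum(axis=0))
            log_p = np.where(n_tot > 0, np.log(n_tot) - log_den, -np.inf)
            # window free energies from the new unbiased distribution
            b = log_p[None, :] + log_b
            b_max = b.max(axis=1)
            f_new = -kT_ * (b_max + np.log(np.exp(b - b_max[:, None]).sum(axis=1)))
            f_new -= f_new[0]
            delta = np.max(np.abs(f_new - f))
            f = f_new
            if delta < tol:
                converged = True
                break

    with np.errstate(divide="ignore", invalid="ignore"):
        pmf = np.where(n_tot > 0, -kT_ * log_p, np.nan)
    support = np.isfinite(pmf)
    idx = np.nonzero(support)[0]
    gap = bool(idx.size) and not np.all(support[idx[0]:idx[-1] + 1])
    if gap:
        warnings.warn("unsupported bins inside the window ladder: "
                      "windows do not overlap", stacklevel=2)
        converged = False

    # zero at the bulk reference: mean over the 2 Å nearest the chosen side
    zs = centers[support]
    if reference_side == "low":
        ref_mask = support & (centers <= zs.min() + 2.0)
    else:
        ref_mask = support & (centers >= zs.max() - 2.0)
    pmf = pmf - np.nanmean(pmf[ref_mask])

    return PMFProfile(z=centers, energy=pmf, window_free_energies=f,
                      converged=converged, iterations=it,
                      meta={"bin_width": bin_width, "temperature": temperature,
                            "reference_side": reference_side})


def _smooth(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return y
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
    return np.convolve(padded, kernel, mode="valid")[:len(y)]


def extract_barriers(pmf: PMFProfile, smooth_width: int = 5,
                     min_prominence: float = 0.3,
                     entrance_side: str = "low") -> BarrierSet:
    """Locate stationary points and report ordered barrier heights.

    ΔE1 is the first maximum above the bulk reference level; ΔE2 the second
    maximum above the well between the first two maxima.  Remaining maxima
    are reported as inter-site barriers, the last one as the exit barrier.
    A monotone profile yields a single barrier max - start.
    """
    m = pmf.supported
    z = pmf.z[m]
    e = _smooth(pmf.energy[m], smooth_width)
    if entrance_side == "high":
        z, e = z[::-1] * -1.0, e[::-1]

    bulk = float(np.mean(e[z <= z.min() + 2.0]))
    pk, _ = find_peaks(e, prominence=min_prominence)
    if len(pk) == 0:
        return BarrierSet(delta_e1=float(e.max() - e[0]), delta_e2=None,
                          inter_site=[], exit_barrier=None,
                          peaks_z=[], wells_z=[], bulk_level=bulk)
    wells = []
    for a, b in zip(pk[:-1], pk[1:]):
        wells.append(a + int(np.argmin(e[a:b + 1])))
    heights = [float(e[pk[0]] - bulk)]
    for w, p in zip(wells, pk[1:]):
        heights.append(float(e[p] - e[w]))
    sign = -1.0 if entrance_side == "high" else 1.0
    return BarrierSet(
        delta_e1=heights[0],
        delta_e2=heights[1] if len(heights) > 1 else None,
        inter_site=heights[2:-1] if len(heights) > 3 else [],
        exit_barrier=heights[-1] if len(heights) > 2 else None,
        peaks_z=[float(sign * z[i]) for i in pk],
        wells_z=[float(sign * z[i]) for i in wells],
        bulk_level=bulk,
    )
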