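"""Packaged analytic reference free-energy profiles.

The two-binding-site channel profiles encode the printed entrance barrier
(ΔE1) and first-binding-site barrier (ΔE2) for Na+ (6.2 / 6.6 kcal/mol) and
K+ (3.1 / 3.5 kcal/mol), together with the qualitative features reported
alongside them: the Na+ inter-site barrier is lower than K+'s and the exit
barriers are similar.  Knots are interpolated with a shape-preserving cubic
(PCHIP) so that the knot extrema are exact and no spurious stationary
points are introduced; energies are zero on the bulk (entrance-side) end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = ["ReferencePMF", "reference_pmf", "REFERENCE_KNOTS"]

# (z Å, energy kcal/mol) knots; ions enter from negative z.
REFERENCE_KNOTS = {
    # ΔE1 = 6.2 (peak @ -6); ΔE2 = 8.6 - 2.0 = 6.6 (peak @ -2 vs well @ -4)
    "na_two_site": [
        (-12, 0.0), (-10, 0.0), (-8, 0.0), (-6, 6.2), (-4, 2.0), (-2, 8.6),
        (0, 2.5), (2, 3.5), (4, 2.0), (6, 4.5), (8, 0.5), (10, 0.0), (12, 0.0),
    ],
    # ΔE1 = 3.1; ΔE2 = 4.5 - 1.0 = 3.5
    "k_two_site": [
        (-12, 0.0), (-10, 0.0), (-8, 0.0), (-6, 3.1), (-4, 1.0), (-2, 4.5),
        (0, 1.5), (2, 4.0), (4, 1.0), (6, 3.5), (8, 0.5), (10, 0.0), (12, 0.0),
    ],
}

_LABELS = {
    "na_two_site": {"bulk": -10.0, "entrance_barrier": -6.0,
                    "entrance_well": -4.0, "site1_barrier": -2.0,
                    "site1": 0.0, "site2": 4.0, "exit": 10.0},
    "k_two_site": {"bulk": -10.0, "entrance_barrier": -6.0,
                   "entrance_well": -4.0, "site1_barrier": -2.0,
                   "site1": 0.0, "site2": 4.0, "exit": 10.0},
}


@dataclass
class ReferencePMF:
    """Analytic 1-D free-energy profile on a z grid (Å, kcal/mol)."""

    z: np.ndarray
    energy: np.ndarray
    labels: dict = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        if not (np.all(np.isfinite(self.z)) and np.all(np.isfinite(self.energy))):
            raise ValueError("non-finite reference profile")

    def __call__(self, z):
        """Interpolated energy; +inf outside the tabulated range."""
        z = np.asarray(z, dtype=float)
        e = np.interp(z, self.z, self.energy)
        out_of_range = (z < self.z[0]) | (z > self.z[-1])
        return np.where(out_of_range, np.inf, e)

    @property
    def z_range(self) -> tuple[float, float]:
        return float(self.z[0]), float(self.z[-1])


def reference_pmf(name: str, dz: float = 0.02) -> ReferencePMF:
    """Packaged profile by name (``na_two_site``, ``k_two_site``)."""
    if name not in REFERENCE_KNOTS:
        raise KeyError(f"unknown reference profile {name!r}; "
                       f"available: {sorted(REFERENCE_KNOTS)}")
    knots = np.array(REFERENCE_KNOTS[name], dtype=float)
    interp = PchipInterpolator(knots[:, 0], knots[:, 1])
    z = np.arange(knots[0, 0], knots[-1, 0] + dz / 2, dz)
    return ReferencePMF(z=z, energy=interp(z), labels=dict(_LABELS[name]),
                        name=name)
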