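"""Axial electrostatic potential of a charged structure.

The potential is a non-periodic direct sum over Gaussian-smeared point
charges in vacuum,

    phi(r) = k_e * sum_i q_i * erf(|r - r_i| / (sqrt(2) sigma)) / |r - r_i|,

which is finite everywhere (the r -> 0 limit is q * sqrt(2/pi) / sigma) and
reduces to the bare Coulomb sum as sigma -> 0.  The 1-D profile is sampled
along the channel axis, optionally averaged over a disc about the axis.
Units are kT/e at the configured temperature by default, volts optionally.
No solvent screening or periodicity is included: the target is the shape
of the channel's interior potential created by the carbonyl decoration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .atoms import AtomSet
from .units import COULOMB_KCAL_A, KCAL_PER_MOL_E_TO_V, kT

__all__ = ["PotentialProfile", "potential_profile", "potential_at_points"]


@dataclass
class PotentialProfile:
    z: np.ndarray
    potential: np.ndarray
    units: str
    smearing: float
    averaging_radius: float
    meta: dict = field(default_factory=dict)


def potential_at_points(atoms: AtomSet, points: np.ndarray,
                        smearing: float = 1.0) -> np.ndarray:
    """Smeared-Coulomb potential at arbitrary points, kcal/mol/e."""
    if smearing <= 0:
        raise ValueError("smearing sigma must be > 0")
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    q = atoms.charges
    # pairwise distances in manageable chunks
    out = np.zeros(len(points))
    denom = np.sqrt(2.0) * smearing
    lim = np.sqrt(2.0 / np.pi) / smearing
    for start in range(0, len(points), 2048):
        p = points[start:start + 2048]
        d = np.linalg.norm(p[:, None, :] - atoms.positions[None, :, :], axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(d > 1e-12, erf(d / denom) / d, lim)
        out[start:start + 2048] = f @ q
    return COULOMB_KCAL_A * out


def potential_profile(atoms: AtomSet, z_grid: np.ndarray | None = None,
                      smearing: float = 1.0, averaging_radius: float = 0.0,
                      n_disc: int = 16, units: str = "kT/e",
                      temperature: float = 300.0) -> PotentialProfile:
    """Axial potential profile phi(z), optionally disc-averaged.

    With ``averaging_radius`` > 0 the potential at each z is averaged over
    ``n_disc`` area-uniform sample points on a disc about the axis.
    """
    if z_grid is None:
        z_grid = np.arange(-12.0, 12.01, 0.25)
    z_grid = np.asarray(z_grid, dtype=float)
    if averaging_radius > 0:
        # sunflower layout: area-uniform points on the disc
        k = np.arange(1, n_disc + 1)
        rad = averaging_radius * np.sqrt((k - 0.5) / n_disc)
        ang = k * 2.399963229728653   # golden angle
        offsets = np.column_stack([rad * np.cos(ang), rad * np.sin(ang),
                                   np.zeros(n_disc)])
    else:
        offsets = np.zeros((1, 3))
    pts = (z_grid[:, None, None] * np.array([0.0, 0.0, 1.0])[None, None, :]
           + offsets[None, :, :]).reshape(-1, 3)
    phi = potential_at_points(atoms, pts, smearing).reshape(len(z_grid),
                                                            len(offsets))
    phi = phi.mean(axis=1)
    if units == "kT/e":
        phi = phi / kT(temperature)
    elif units in ("V", "volts"):
        phi = phi * KCAL_PER_MOL_E_TO_V
    elif units != "kcal/mol/e":
        raise ValueError(f"unknown units {units!r}")
    return PotentialProfile(z=z_grid, potential=phi, units=units,
                            smearing=smearing,
                            averaging_radius=averaging_radius,
                            meta={"temperature": temperature})
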