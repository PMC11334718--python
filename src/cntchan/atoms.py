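"""Core containers: typed atomic structures and trajectories.

An :class:`AtomSet` is a flat, array-backed collection of atoms carrying an
element symbol, Cartesian position (Å), partial charge (e) and a *group tag*
drawn from a closed vocabulary (channel wall carbon, carbonyl C/O, graphene,
water sites, ions).  A :class:`Trajectory` stores frames of a fixed particle
roster with per-frame times (ns) and an optional orthorhombic box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Closed vocabulary of per-atom group tags.
GROUP_TAGS = (
    "wall_C",
    "carbonyl_C",
    "carbonyl_O",
    "graphene_C",
    "water_O",
    "water_H",
    "ion_K",
    "ion_Na",
    "ion_Cl",
)

#: Default element symbol for each group tag.
TAG_ELEMENTS = {
    "wall_C": "C",
    "carbonyl_C": "C",
    "carbonyl_O": "O",
    "graphene_C": "C",
    "water_O": "O",
    "water_H": "H",
    "ion_K": "K",
    "ion_Na": "Na",
    "ion_Cl": "Cl",
}

#: Fallback tag inferred from a bare element symbol (tag-less files).
ELEMENT_TAGS = {
    "C": "wall_C",
    "O": "water_O",
    "H": "water_H",
    "K": "ion_K",
    "Na": "ion_Na",
    "Cl": "ion_Cl",
}


@dataclass
class AtomSet:
    """Typed atomic structure: elements, positions (Å), charges (e), tags."""

    elements: np.ndarray
    positions: np.ndarray
    charges: np.ndarray
    tags: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        self.tags = np.asarray(self.tags, dtype=object)
        n = len(self.positions)
        if not (len(self.elements) == len(self.charges) == len(self.tags) == n):
            raise ValueError("AtomSet arrays must have equal lengths")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        bad = set(self.tags) - set(GROUP_TAGS)
        if bad:
            raise ValueError(f"unknown group tags: {sorted(bad)}")

    @classmethod
    def from_tags(cls, tags, positions, charges=None, meta=None) -> "AtomSet":
        tags = np.asarray(tags, dtype=object)
        elements = np.array([TAG_ELEMENTS[t] for t in tags], dtype=object)
        if charges is None:
            charges = np.zeros(len(tags))
        return cls(elements, positions, charges, tags, meta or {})

    @classmethod
    def empty(cls) -> "AtomSet":
        return cls(np.empty(0, object), np.empty((0, 3)), np.empty(0),
                   np.empty(0, object))

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def copy(self) -> "AtomSet":
        return AtomSet(self.elements.copy(), self.positions.copy(),
                       self.charges.copy(), self.tags.copy(), dict(self.meta))

    def mask(self, *tags: str) -> np.ndarray:
        """Boolean mask of atoms whose group tag is in ``tags``."""
        return np.isin(self.tags.astype(str), tags)

    def select(self, *tags: str) -> "AtomSet":
        m = self.mask(*tags)
        return AtomSet(self.elements[m], self.positions[m], self.charges[m],
                       self.tags[m], dict(self.meta))

    def net_charge(self) -> float:
        return float(self.charges.sum())

    @staticmethod
    def concat(*sets: "AtomSet") -> "AtomSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            return AtomSet.empty()
        meta: dict = {}
        for s in sets:
            meta.update(s.meta)
        return AtomSet(
            np.concatenate([s.elements for s in sets]),
            np.concatenate([s.positions for s in sets]),
            np.concatenate([s.charges for s in sets]),
            np.concatenate([s.tags for s in sets]),
            meta,
        )


@dataclass
class Trajectory:
    """Frames of a fixed particle roster.

    positions: (n_frames, n_atoms, 3) in Å; times: (n_frames,) in ns.
    """

    positions: np.ndarray
    tags: np.ndarray
    elements: np.ndarray
    times: np.ndarray
    box: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must be (n_frames, n_atoms, 3)")
        self.tags = np.asarray(self.tags, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.times = np.asarray(self.times, dtype=float)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
        if len(self.tags) != self.positions.shape[1]:
            raise ValueError("tags do not match atom count")
        if len(self.times) != self.positions.shape[0]:
            raise ValueError("times do not match frame count")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def frame_dt(self) -> float:
        if self.n_frames < 2:
            return float(self.meta.get("frame_dt", 0.0))
        return float(self.times[1] - self.times[0])

    def mask(self, *tags: str) -> np.ndarray:
        return np.isin(self.tags.astype(str), tags)

    def atom_indices(self, *tags: str) -> np.ndarray:
        return np.nonzero(self.mask(*tags))[0]

    def subsample(self, stride: int) -> "Trajectory":
        """Every ``stride``-th frame (analysis-resolution invariance checks)."""
        return Trajectory(self.positions[::stride], self.tags, self.elements,
                          self.times[::stride], self.box, dict(self.meta))

    @classmethod
    def from_atomset(cls, atoms: AtomSet, box=None, time: float = 0.0
                     ) -> "Trajectory":
        """Single-frame trajectory wrapping a static structure."""
        return cls(atoms.positions[None, :, :], atoms.tags, atoms.elements,
                   np.array([time]), box)

    def frame(self, i: int, charges=None) -> AtomSet:
        if charges is None:
            charges = np.zeros(self.n_atoms)
        return AtomSet(self.elements, self.positions[i], charges, self.tags)
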