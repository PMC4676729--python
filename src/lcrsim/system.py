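"""Bead-chain system containers for the one-bead-per-residue model.

A :class:`System` holds everything the force field and integrator need:
bead positions, masses, charges, hydrophobicities, chain topology (chains are
contiguous index ranges; consecutive beads are bonded), tether constraints
(anchored beads are realized by freezing them: infinite-mass convention,
``inv_mass = 0``), and an optional rigid scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


@dataclass
class Scaffold:
    """Rigid excluded-volume scaffold: an hourglass surface of revolution
    plus optional spherical blobs.

    The wall radius follows a parabolic profile about the waist,
    ``R(z) = r_waist + (r_end - r_waist) * (z / half_length)**2`` for
    ``|z| <= half_length``; beads are confined to ``rho < R(z)`` by a
    harmonic penalty that engages within ``contact`` of the wall.  Blobs are
    spheres given as rows ``(cx, cy, cz, radius)`` that repel beads the same
    way.  The scaffold exerts excluded-volume forces only.
    """

    r_waist: float = 20.0
    r_end: float = 35.0
    half_length: float = 17.5
    contact: float = 0.3
    k_wall: float = 500.0
    blobs: np.ndarray = field(default_factory=lambda: np.zeros((0, 4)))

    def radius_at(self, z: float) -> float:
        return self.r_waist + (self.r_end - self.r_waist) * (z / self.half_length) ** 2


@dataclass
class System:
    """Beads, chain topology, tethers, and optional scaffold."""

    positions: np.ndarray            # (N, 3) nm
    masses: np.ndarray               # (N,) Da
    charges: np.ndarray              # (N,) e
    hydrophobicity: np.ndarray       # (N,) in [0, 1]
    chain_id: np.ndarray             # (N,) int, chains are contiguous
    fixed: np.ndarray                # (N,) bool, tethered beads
    fg_markers: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    scaffold: Scaffold | None = None
    confine_radius: float = 0.0      # optional reflecting outer cylinder, 0 = off
    names: tuple[str, ...] = ()      # one label per chain
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        n = len(self.positions)
        for name in ("masses", "charges", "hydrophobicity", "chain_id", "fixed"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        self.chain_id = np.ascontiguousarray(self.chain_id, dtype=np.int64)
        self.fixed = np.ascontiguousarray(self.fixed, dtype=bool)
        self.fg_markers = np.ascontiguousarray(self.fg_markers, dtype=np.int64)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_chains(self) -> int:
        return len(np.unique(self.chain_id))

    def chain_slices(self) -> list[slice]:
        """Contiguous index range of each chain, in chain order."""
        out = []
        ids = self.chain_id
        start = 0
        for i in range(1, len(ids) + 1):
            if i == len(ids) or ids[i] != ids[start]:
                out.append(slice(start, i))
                start = i
        return out

    def bonds(self) -> np.ndarray:
        """(M, 2) bonded bead pairs: consecutive beads within each chain."""
        pairs = []
        for sl in self.chain_slices():
            idx = np.arange(sl.start, sl.stop)
            pairs.append(np.column_stack([idx[:-1], idx[1:]]))
        if not pairs:
            return np.zeros((0, 2), dtype=np.int64)
        return np.concatenate(pairs).astype(np.int64)

    def angles(self) -> np.ndarray:
        """(M, 3) bending triplets of consecutive beads."""
        out = []
        for sl in self.chain_slices():
            idx = np.arange(sl.start, sl.stop)
            if len(idx) >= 3:
                out.append(np.column_stack([idx[:-2], idx[1:-1], idx[2:]]))
        if not out:
            return np.zeros((0, 3), dtype=np.int64)
        return np.concatenate(out).astype(np.int64)

    def dihedrals(self) -> np.ndarray:
        """(M, 4) torsion quadruplets of consecutive beads."""
        out = []
        for sl in self.chain_slices():
            idx = np.arange(sl.start, sl.stop)
            if len(idx) >= 4:
                out.append(
                    np.column_stack([idx[:-3], idx[1:-2], idx[2:-1], idx[3:]])
                )
        if not out:
            return np.zeros((0, 4), dtype=np.int64)
        return np.concatenate(out).astype(np.int64)

    def copy(self) -> "System":
        return replace(
            self,
            positions=self.positions.copy(),
            masses=self.masses.copy(),
            charges=self.charges.copy(),
            hydrophobicity=self.hydrophobicity.copy(),
            chain_id=self.chain_id.copy(),
            fixed=self.fixed.copy(),
            fg_markers=self.fg_markers.copy(),
            meta=dict(self.meta),
        )
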