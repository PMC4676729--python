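"""Force-field parameters and evaluation for the one-bead-per-residue model.

Each residue is a single bead of 120 Da spaced 0.38 nm along the chain.  The
potential is the sum of

* a stiff harmonic bond about 0.38 nm (surrogate for a rigid constraint),
* bending (harmonic in the angle by default) and torsion (cosine series)
  between neighboring beads, either of which can be replaced by a tabulated
  potential, e.g. one Boltzmann-inverted from atomistic statistics,
* a two-part modified Lennard-Jones pair term: WCA excluded-volume repulsion
  plus an attractive tail whose depth scales with the combined
  hydrophobicity of the two residues,
* Debye-Hückel screened electrostatics (screening length 1/kappa) between
  charged beads.

Van der Waals and Coulomb interactions are cut off at 2.5 and 5.0 nm and
shifted so the energy is continuous at the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from ._kernels import KB, COULOMB_F
from .system import System

#: Default per-residue hydrophobicity on [0, 1]: the positive part of the
#: Kyte-Doolittle hydropathy index, h = max(KD, 0) / 4.5.  Polar and charged
#: residues are non-attractive (h = 0), so FG-Nup spacers behave as a
#: good-solvent background while F/A/L/I/V-driven contacts provide the
#: cohesion; any dict mapping the 20 residues to [0, 1] may be substituted.
HYDROPHOBICITY: dict[str, float] = {
    "A": 0.400, "R": 0.000, "N": 0.000, "D": 0.000, "C": 0.556,
    "Q": 0.000, "E": 0.000, "G": 0.000, "H": 0.000, "I": 1.000,
    "L": 0.844, "K": 0.000, "M": 0.422, "F": 0.622, "P": 0.000,
    "S": 0.000, "T": 0.000, "W": 0.000, "V": 0.933, "Y": 0.000,
}

_EMPTY = np.zeros(2)
_EMPTY_IDX = np.zeros(0, dtype=np.int64)
_EMPTY_PAIRS = (_EMPTY_IDX, _EMPTY_IDX, 0, _EMPTY_IDX, _EMPTY_IDX, 0)


@dataclass
class ForceFieldParams:
    """All tunable constants of the model (nm, ps, kJ/mol, Da, e)."""

    bond_length: float = 0.38
    bond_k: float = 8000.0
    bead_mass: float = 120.0
    kappa: float = 1.0               # Debye screening parameter, nm^-1
    r_cut_vdw: float = 2.5
    r_cut_coul: float = 5.0
    temperature: float = 300.0
    dielectric: float = 80.0
    lj_sigma: float = 0.6            # excluded-volume diameter
    eps_rep: float = 1.0             # WCA repulsive strength
    eps_hp_max: float = 7.0          # max hydrophobic well depth
    hp_combination: str = "geometric"    # or "arithmetic"
    bend_k: float = 4.0              # kJ/mol/rad^2
    bend_theta0: float = 2.094       # 120 degrees
    torsion_terms: tuple = ((0.5, 1, 0.0),)  # (k, multiplicity, phi0) series
    bend_table: tuple | None = None      # (theta_grid, U) overrides harmonic
    torsion_table: tuple | None = None   # (phi_grid, U) overrides cosine series
    exclusion_depth: int = 1         # bonded pairs excluded from nonbonded terms
    skin: float = 0.3                # Verlet-list skin, nm
    hydrophobicity_scale: dict = field(default_factory=lambda: dict(HYDROPHOBICITY))

    def __post_init__(self) -> None:
        if self.r_cut_vdw <= 0 or self.r_cut_coul <= 0 or self.bond_length <= 0:
            raise ValueError("lengths and cutoffs must be positive")
        if self.r_cut_vdw > self.r_cut_coul:
            raise ValueError("r_cut_vdw must not exceed r_cut_coul")
        for aa, v in self.hydrophobicity_scale.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"hydrophobicity of {aa} outside [0, 1]: {v}")
        if self.hp_combination not in ("arithmetic", "geometric"):
            raise ValueError(f"unknown combination rule {self.hp_combination!r}")

    @property
    def kT(self) -> float:
        return KB * self.temperature

    @property
    def coul_c(self) -> float:
        """Coulomb prefactor C in U = C q_i q_j exp(-kappa r)/r, kJ·nm/mol."""
        return COULOMB_F / self.dielectric

    def copy(self, **changes) -> "ForceFieldParams":
        return replace(self, **changes)


def _table_arrays(table):
    """Uniform-grid (x, U) table -> (x0, dx, U, dU) for Hermite evaluation."""
    if table is None:
        return 0.0, 1.0, _EMPTY, _EMPTY
    x, u = np.asarray(table[0], float), np.asarray(table[1], float)
    dx = np.diff(x)
    if not np.allclose(dx, dx[0]):
        raise ValueError("tabulated potential requires a uniform grid")
    du = np.gradient(u, x[1] - x[0])
    return float(x[0]), float(x[1] - x[0]), u, du


class ForceField:
    """Marshals a ``System`` + ``ForceFieldParams`` into kernel calls."""

    def __init__(self, system: System, params: ForceFieldParams):
        self.system = system
        self.params = params
        self.bonds = system.bonds()
        self.angles = system.angles()
        self.dihedrals = system.dihedrals()
        p = params
        bx0, bdx, bu, bdu = _table_arrays(p.bend_table)
        tx0, tdx, tu, tdu = _table_arrays(p.torsion_table)
        tors = np.asarray(p.torsion_terms, float).reshape(-1, 3)
        self._bonded_args = (
            self.bonds, p.bond_k, p.bond_length,
            self.angles, 0 if p.bend_table is None else 1,
            p.bend_k, p.bend_theta0, bx0, bdx, bu, bdu,
            self.dihedrals, 0 if p.torsion_table is None else 1,
            np.ascontiguousarray(tors[:, 0]), np.ascontiguousarray(tors[:, 1]),
            np.ascontiguousarray(tors[:, 2]), tx0, tdx, tu, tdu,
        )
        sc = system.scaffold
        self._nonbonded_args = (
            p.lj_sigma, p.eps_rep, p.eps_hp_max,
            p.hp_combination == "geometric",
            np.ascontiguousarray(system.hydrophobicity, float),
            np.ascontiguousarray(np.sqrt(system.hydrophobicity), float),
            np.ascontiguousarray(system.charges, float),
            p.coul_c, p.kappa, p.r_cut_vdw, p.r_cut_coul,
            sc is not None,
            sc.r_waist if sc else 0.0, sc.r_end if sc else 0.0,
            sc.half_length if sc else 1.0, sc.contact if sc else 0.0,
            sc.k_wall if sc else 0.0,
            np.ascontiguousarray(sc.blobs, float) if sc is not None
            else np.zeros((0, 4)),
            system.confine_radius, 100.0,
        )
        self.charged = np.ascontiguousarray(system.charges != 0.0)
        self.all_active = np.ones(system.n_beads, dtype=bool)
        self.cutoff_vdw_list = p.r_cut_vdw + p.skin
        self.cutoff_coul_list = p.r_cut_coul + p.skin
        self._cap_vdw = max(64 * system.n_beads, 1024)
        self._cap_coul = max(64 * int(self.charged.sum()), 1024)

    def build_pair_list(self, pos: np.ndarray):
        """Verlet pair lists (vdW over all beads, Coulomb over charged beads)
        within cutoff + skin; storage grows on demand."""
        while True:
            pi = np.empty(self._cap_vdw, dtype=np.int64)
            pj = np.empty(self._cap_vdw, dtype=np.int64)
            n = _kernels.build_pairs(
                pos, self.system.chain_id, self.params.exclusion_depth,
                self.cutoff_vdw_list, self.all_active, pi, pj,
            )
            if n >= 0:
                break
            self._cap_vdw *= 2
        while True:
            ci = np.empty(self._cap_coul, dtype=np.int64)
            cj = np.empty(self._cap_coul, dtype=np.int64)
            m = _kernels.build_pairs(
                pos, self.system.chain_id, self.params.exclusion_depth,
                self.cutoff_coul_list, self.charged, ci, cj,
            )
            if m >= 0:
                return pi, pj, n, ci, cj, m
            self._cap_coul *= 2

    def energy_forces(
        self,
        pos: np.ndarray,
        pairs=None,
        do_angles: bool = True,
        do_att: bool = True,
        do_elec: bool = True,
    ):
        """Total energy and per-bead forces at ``pos``.

        Term masks exist for the staged minimization protocol: bonds, WCA
        repulsion, and scaffold are always on; ``do_angles`` gates
        bending+torsion, ``do_att`` the hydrophobic tail, ``do_elec`` the
        electrostatics.
        """
        pos = np.ascontiguousarray(pos, float)
        if pairs is None:
            pairs = self.build_pair_list(pos)
        pi, pj, npairs, ci, cj, ncoul = pairs
        forces = np.empty_like(pos)
        energy = _kernels.compute_forces(
            pos, forces, *self._bonded_args, pi, pj, npairs, ci, cj, ncoul,
            *self._nonbonded_args, do_angles, do_att, do_elec,
        )
        return energy, forces


def beads_from_sequence(seq, params: ForceFieldParams, convention=None):
    """Per-bead (masses, charges, hydrophobicities) for one sequence."""
    from .sequences import assign_charges

    n = len(seq.residues)
    masses = np.full(n, params.bead_mass)
    charges = assign_charges(seq, convention).astype(float)
    scale = params.hydrophobicity_scale
    h = np.array([scale[aa] for aa in seq.residues])
    return masses, charges, h


# ---------------------------------------------------------------------------
# Single-term reference evaluations (closed forms mirrored by the kernels)
# ---------------------------------------------------------------------------

def lj_two_part(r: float, sigma: float, eps_rep: float, eps_hp: float,
                r_cut: float):
    """Two-part Lennard-Jones pair potential: (energy, scalar force).

    WCA repulsion of strength ``eps_rep`` for r below the LJ minimum, plus an
    attractive tail of depth ``eps_hp``; truncated and shifted to zero at
    ``r_cut``.  The scalar force is -dU/dr (positive = repulsive).
    """
    if r <= 0:
        raise ValueError("r must be positive (overlapping beads)")
    if r >= r_cut:
        return 0.0, 0.0
    rmin = 2.0 ** (1.0 / 6.0) * sigma
    sr6 = (sigma / r) ** 6
    lj = 4.0 * (sr6 * sr6 - sr6)
    dljdr = -(48.0 * sr6 * sr6 - 24.0 * sr6) / r
    sr6c = (sigma / r_cut) ** 6
    ljc = 4.0 * (sr6c * sr6c - sr6c)
    if r < rmin:
        return eps_rep * (lj + 1.0) + eps_hp * (-1.0 - ljc), -eps_rep * dljdr
    return eps_hp * (lj - ljc), -eps_hp * dljdr


def debye_huckel(r: float, qi: float, qj: float, params: ForceFieldParams,
                 shifted: bool = True):
    """Screened-Coulomb pair potential: (energy, scalar force).

    U = C q_i q_j exp(-kappa r) / r with C = f / dielectric; truncated (and,
    by default, shifted to zero) at the Coulomb cutoff.
    """
    if r <= 0:
        raise ValueError("r must be positive (overlapping beads)")
    qq = qi * qj
    if qq == 0.0 or r >= params.r_cut_coul:
        return 0.0, 0.0
    pref = params.coul_c * qq
    e = pref * np.exp(-params.kappa * r) / r
    if shifted:
        e -= pref * np.exp(-params.kappa * params.r_cut_coul) / params.r_cut_coul
    f = pref * np.exp(-params.kappa * r) * (params.kappa * r + 1.0) / r**2
    return e, f


def bond_energy_forces(pos, system: System, params: ForceFieldParams):
    """Bond-term-only energy and forces (harmonic about 0.38 nm)."""
    ff = ForceField(system, params.copy(eps_rep=0.0, eps_hp_max=0.0))
    return ff.energy_forces(pos, pairs=_EMPTY_PAIRS, do_angles=False,
                            do_att=False, do_elec=False)


def bending_torsion_energy_forces(pos, system: System, params: ForceFieldParams):
    """Bending + torsion energy and forces only."""
    ff = ForceField(system, params.copy(bond_k=0.0))
    return ff.energy_forces(pos, pairs=_EMPTY_PAIRS, do_angles=True,
                            do_att=False, do_elec=False)


def total_energy_forces(pos, system: System, params: ForceFieldParams):
    """Full-potential energy and forces with a fresh pair list."""
    return ForceField(system, params).energy_forces(pos)
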