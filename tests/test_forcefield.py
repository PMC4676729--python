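"""Force-field correctness: closed forms, gradients, symmetries, cutoffs."""

import numpy as np
import pytest

from lcrsim.forcefield import (
    ForceField,
    ForceFieldParams,
    bond_energy_forces,
    bending_torsion_energy_forces,
    debye_huckel,
    lj_two_part,
    total_energy_forces,
)
from lcrsim.geometry import build_single
from lcrsim.sequences import NupSequence
from lcrsim.system import Scaffold, System


def chain_system(n, charges=None, h=None, seed=0):
    rng = np.random.default_rng(seed)
    pos = np.cumsum(0.38 * _unit_rows(rng, n), axis=0)
    return System(
        positions=pos,
        masses=np.full(n, 120.0),
        charges=np.zeros(n) if charges is None else np.asarray(charges, float),
        hydrophobicity=np.zeros(n) if h is None else np.asarray(h, float),
        chain_id=np.zeros(n, dtype=np.int64),
        fixed=np.zeros(n, dtype=bool),
    )


def _unit_rows(rng, n):
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def numeric_gradient(fn, pos, h=1e-6):
    out = np.zeros_like(pos)
    for i in range(pos.shape[0]):
        for k in range(3):
            pp, pm = pos.copy(), pos.copy()
            pp[i, k] += h
            pm[i, k] -= h
            out[i, k] = -(fn(pp) - fn(pm)) / (2 * h)
    return out


class TestBondTerm:
    def test_equilibrium_is_zero(self):
        sys_ = chain_system(2)
        sys_.positions = np.array([[0.0, 0, 0], [0.38, 0, 0]])
        e, f = bond_energy_forces(sys_.positions, sys_, ForceFieldParams())
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(f, 0.0, atol=1e-9)

    def test_harmonic_closed_form(self):
        sys_ = chain_system(2)
        sys_.positions = np.array([[0.0, 0, 0], [0.48, 0, 0]])
        p = ForceFieldParams()
        e, _ = bond_energy_forces(sys_.positions, sys_, p)
        assert e == pytest.approx(0.5 * p.bond_k * 0.1**2, rel=1e-9)

    def test_net_force_vanishes(self):
        sys_ = chain_system(10, seed=3)
        _, f = bond_energy_forces(sys_.positions, sys_, ForceFieldParams())
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-10)


class TestBendingTorsion:
    def test_collinear_triplet_zero_bending(self):
        sys_ = chain_system(3)
        sys_.positions = np.array([[0.0, 0, 0], [0.38, 0, 0], [0.76, 0, 0]])
        p = ForceFieldParams(bend_theta0=np.pi, torsion_terms=((0.0, 1, 0.0),))
        e, _ = bending_torsion_energy_forces(sys_.positions, sys_, p)
        assert e == pytest.approx(0.0, abs=1e-10)

    def test_isolated_triplet_net_force_and_torque_vanish(self):
        sys_ = chain_system(3, seed=5)
        _, f = bending_torsion_energy_forces(
            sys_.positions, sys_, ForceFieldParams())
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-10)
        torque = np.cross(sys_.positions, f).sum(axis=0)
        assert np.allclose(torque, 0.0, atol=1e-10)

    @pytest.mark.parametrize("tabulated", [False, True])
    def test_gradient_matches_finite_differences(self, tabulated):
        if tabulated:
            th = np.linspace(0.1, np.pi, 50)
            ph = np.linspace(-np.pi, np.pi, 72)
            p = ForceFieldParams(
                bend_table=(th, 1.5 * (th - 1.8) ** 2),
                torsion_table=(ph, 0.7 * np.cos(ph) + 0.2 * np.sin(2 * ph)),
            )
        else:
            p = ForceFieldParams()
        sys_ = chain_system(6, seed=7)
        e, f = bending_torsion_energy_forces(sys_.positions, sys_, p)
        num = numeric_gradient(
            lambda x: bending_torsion_energy_forces(x, sys_, p)[0],
            sys_.positions,
        )
        assert np.max(np.abs(num - f)) / np.max(np.abs(f)) < 1e-6


class TestTwoPartLJ:
    def test_pure_excluded_volume_when_no_hydrophobicity(self):
        p = ForceFieldParams()
        rmin = 2 ** (1 / 6) * p.lj_sigma
        for r in np.linspace(0.3, 2.4, 40):
            e, _ = lj_two_part(r, p.lj_sigma, p.eps_rep, 0.0, p.r_cut_vdw)
            if r < rmin:
                assert e > 0
            else:
                assert e == pytest.approx(0.0, abs=1e-12)

    def test_zero_at_cutoff_and_continuous(self):
        p = ForceFieldParams()
        e, _ = lj_two_part(p.r_cut_vdw - 1e-9, p.lj_sigma, p.eps_rep, 1.3,
                           p.r_cut_vdw)
        assert abs(e) < 1e-6
        # continuity at the WCA/tail seam
        rmin = 2 ** (1 / 6) * p.lj_sigma
        lo, _ = lj_two_part(rmin - 1e-9, p.lj_sigma, p.eps_rep, 1.3, p.r_cut_vdw)
        hi, _ = lj_two_part(rmin + 1e-9, p.lj_sigma, p.eps_rep, 1.3, p.r_cut_vdw)
        assert lo == pytest.approx(hi, abs=1e-6)

    def test_well_depth_scales_with_hydrophobicity(self):
        p = ForceFieldParams()
        rmin = 2 ** (1 / 6) * p.lj_sigma
        e1, _ = lj_two_part(rmin, p.lj_sigma, p.eps_rep, 1.0, p.r_cut_vdw)
        e2, _ = lj_two_part(rmin, p.lj_sigma, p.eps_rep, 2.0, p.r_cut_vdw)
        assert e2 < e1 < 0

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            lj_two_part(0.0, 0.6, 1.0, 1.0, 2.5)

    def test_combination_rule_symmetry(self, rng):
        sys_ = chain_system(2)
        for rule in ("arithmetic", "geometric"):
            p = ForceFieldParams(hp_combination=rule)
            for _ in range(100):
                h1, h2 = rng.random(2)
                sys_.hydrophobicity = np.array([h1, h2])
                ff = ForceField(sys_, p)
                e12, _ = ff.energy_forces(sys_.positions)
                sys_.hydrophobicity = np.array([h2, h1])
                ff = ForceField(sys_, p)
                e21, _ = ff.energy_forces(sys_.positions)
                assert e12 == pytest.approx(e21, rel=1e-12)


class TestDebyeHuckel:
    def test_zero_charge_zero_energy(self):
        e, f = debye_huckel(1.0, 0.0, 1.0, ForceFieldParams())
        assert (e, f) == (0.0, 0.0)

    def test_zero_beyond_cutoff(self):
        p = ForceFieldParams()
        e, f = debye_huckel(p.r_cut_coul, 1.0, 1.0, p)
        assert (e, f) == (0.0, 0.0)

    def test_screened_ratio_closed_form(self):
        """U(2 nm) / U(1 nm) = (1/2) e^-kappa for the unshifted potential."""
        p = ForceFieldParams(kappa=1.0)
        e1, _ = debye_huckel(1.0, 1.0, 1.0, p, shifted=False)
        e2, _ = debye_huckel(2.0, 1.0, 1.0, p, shifted=False)
        assert e2 / e1 == pytest.approx(0.5 * np.exp(-1.0), rel=1e-12)

    def test_sign_convention(self):
        p = ForceFieldParams()
        like, _ = debye_huckel(0.8, 1.0, 1.0, p)
        unlike, _ = debye_huckel(0.8, 1.0, -1.0, p)
        assert like > 0 > unlike


class TestTotalEnergyForces:
    def test_single_bead_zero_energy(self):
        sys_ = chain_system(1)
        e, f = total_energy_forces(sys_.positions, sys_, ForceFieldParams())
        assert e == 0.0
        assert np.allclose(f, 0.0)

    def test_neutral_bonded_pair_at_equilibrium(self):
        sys_ = chain_system(2)
        sys_.positions = np.array([[0.0, 0, 0], [0.38, 0, 0]])
        p = ForceFieldParams(torsion_terms=((0.0, 1, 0.0),))
        e, _ = total_energy_forces(sys_.positions, sys_, p)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_neighbor_list_matches_all_pairs(self):
        """Kernel evaluation through the Verlet list equals a brute-force
        O(N^2) pairwise sum of the same closed-form pair potentials."""
        rng = np.random.default_rng(11)
        n = 50
        sys_ = chain_system(n, charges=rng.choice([-1, 0, 0, 1], n),
                            h=rng.random(n), seed=13)
        p = ForceFieldParams()
        ff = ForceField(sys_, p)
        pos = sys_.positions
        e_kernel, _ = ff.energy_forces(pos, do_angles=False)
        # independent all-pairs accumulation from the scalar closed forms
        e_brute = 0.0
        rmin_seen = np.inf
        for i in range(n):
            for j in range(i + 1, n):
                r = np.linalg.norm(pos[i] - pos[j])
                rmin_seen = min(rmin_seen, r)
                if j - i <= p.exclusion_depth:
                    continue
                eps_hp = p.eps_hp_max * 0.5 * (
                    sys_.hydrophobicity[i] + sys_.hydrophobicity[j])
                e_brute += lj_two_part(r, p.lj_sigma, p.eps_rep, eps_hp,
                                       p.r_cut_vdw)[0]
                e_brute += debye_huckel(r, sys_.charges[i], sys_.charges[j], p)[0]
        # remove the bond-term energy computed by the kernel
        e_bonds, _ = bond_energy_forces(pos, sys_, p)
        assert e_kernel - e_bonds == pytest.approx(e_brute, rel=1e-9)

    def test_zero_charge_zero_h_reduces_to_excluded_volume(self):
        sys_ = chain_system(20, seed=17)
        p = ForceFieldParams(torsion_terms=((0.0, 1, 0.0),), bend_k=0.0)
        e_full, _ = total_energy_forces(sys_.positions, sys_, p)
        ff = ForceField(sys_, p)
        e_wca, _ = ff.energy_forces(sys_.positions, do_att=False, do_elec=False)
        assert e_full == pytest.approx(e_wca, rel=1e-12)
        assert e_full >= 0.0

    def test_isolated_system_net_force_zero(self):
        sys_ = build_single(NupSequence("t", "SKFGDNTAKEFGSQRLIVKDES"), seed=19)
        _, f = total_energy_forces(sys_.positions, sys_, ForceFieldParams())
        scale = max(np.max(np.abs(f)), 1.0)
        assert np.allclose(f.sum(axis=0) / scale, 0.0, atol=1e-12)


class TestGradients:
    """Analytic forces vs central differences for the full potential on
    random disordered configurations, including scaffold and confinement."""

    def test_full_potential_gradient(self):
        rng = np.random.default_rng(23)
        seq = NupSequence("t", "SKFGDNTAKEFGSQRLIV")
        sys_ = build_single(seq, seed=29)
        sys_.scaffold = Scaffold(r_waist=2.5, r_end=4.0, half_length=3.0,
                                 blobs=np.array([[1.5, 0.0, 0.0, 0.8]]))
        sys_.confine_radius = 3.0
        p = ForceFieldParams()
        ff = ForceField(sys_, p)
        for _ in range(5):
            pos = sys_.positions + 0.05 * rng.standard_normal(sys_.positions.shape)
            e, f = ff.energy_forces(pos)
            num = numeric_gradient(lambda x: ff.energy_forces(x)[0], pos)
            rel = np.max(np.abs(num - f)) / np.max(np.abs(f))
            assert rel < 1e-6

    def test_pairwise_force_antisymmetry(self):
        """Two isolated beads: force on i equals minus force on j for both
        the hydrophobic and electrostatic terms."""
        sys_ = chain_system(2, charges=[1.0, 1.0], h=[0.5, 0.9])
        sys_.chain_id = np.array([0, 1])  # unbonded pair
        p = ForceFieldParams()
        ff = ForceField(sys_, p)
        for r in (0.5, 0.7, 1.5, 3.0):
            pos = np.array([[0.0, 0, 0], [r, 0, 0]])
            _, f = ff.energy_forces(pos, do_angles=False)
            assert np.allclose(f[0], -f[1], atol=1e-12)
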