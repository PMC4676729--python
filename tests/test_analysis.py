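"""Readout correctness: end-to-end distance, RMSD, density grids, and
comparison statistics."""

import numpy as np
import pytest
from scipy import stats

from lcrsim.analysis import (
    DensityGrid,
    DensityGridSpec,
    MetricSeries,
    cells_per_radial_bin,
    compare_metric,
    end_to_end,
    fg_density,
    max_density_change,
    merge_grids,
    radial_axial_profile,
    rmsd,
)
from lcrsim.simulator import SimulationParams, Trajectory


def make_traj(frames):
    frames = np.asarray(frames, float)
    return Trajectory(
        frames=frames,
        times=np.arange(len(frames), dtype=float),
        params=SimulationParams(),
        seed=0,
    )


class TestEndToEnd:
    def test_two_beads(self):
        traj = make_traj([[[0, 0, 0], [0.38, 0, 0]]])
        assert end_to_end(traj, (0, 2)).values[0] == pytest.approx(0.38)

    def test_straight_chain(self):
        frames = np.zeros((1, 11, 3))
        frames[0, :, 0] = 0.38 * np.arange(11)
        assert end_to_end(make_traj(frames), (0, 11)).values[0] == pytest.approx(3.8)

    def test_single_bead_range_is_zero(self):
        traj = make_traj(np.random.default_rng(0).standard_normal((3, 5, 3)))
        assert np.allclose(end_to_end(traj, (2, 3)).values, 0.0)

    def test_range_spanning_chains_rejected(self):
        traj = make_traj(np.zeros((1, 4, 3)))
        with pytest.raises(ValueError, match="chain"):
            end_to_end(traj, (0, 4), chain_id=np.array([0, 0, 1, 1]))


class TestRmsd:
    def test_identity_is_zero(self):
        frames = np.random.default_rng(1).standard_normal((1, 10, 3))
        traj = make_traj(np.repeat(frames, 3, axis=0))
        assert np.allclose(rmsd(traj, 0, (0, 10)).values, 0.0, atol=1e-9)

    def test_rigid_rotation_removed_by_alignment(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal((12, 3))
        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        traj = make_traj([base, base @ rot.T + 5.0])
        aligned = rmsd(traj, 0, (0, 12), align=True)
        raw = rmsd(traj, 0, (0, 12), align=False)
        assert aligned.values[1] == pytest.approx(0.0, abs=1e-9)
        assert raw.values[1] > 1.0

    def test_single_displaced_bead_closed_form(self):
        base = np.zeros((8, 3))
        base[:, 0] = np.arange(8.0)
        moved = base.copy()
        moved[3, 1] += 0.9
        traj = make_traj([base, moved])
        expected = np.sqrt(0.9**2 / 8)
        assert rmsd(traj, 0, (0, 8), align=False).values[1] == pytest.approx(expected)

    def test_matches_mdtraj_superposed(self):
        """Kabsch superposition agrees with an established implementation."""
        mdtraj = pytest.importorskip("mdtraj")
        rng = np.random.default_rng(3)
        frames = rng.standard_normal((5, 20, 3))
        traj = make_traj(frames)
        ours = rmsd(traj, 0, (0, 20), align=True).values
        top = mdtraj.Topology()
        ch = top.add_chain()
        for i in range(20):
            res = top.add_residue("GLY", ch)
            top.add_atom("CA", mdtraj.element.carbon, res)
        mt = mdtraj.Trajectory(frames, top)
        theirs = mdtraj.rmsd(mt, mt, 0)
        assert np.allclose(ours, theirs, atol=1e-5)


class TestFgDensity:
    spec = DensityGridSpec(diameter=10.0, length=4.0, cell=0.5)

    def test_immobile_marker_single_cell(self):
        frames = np.tile(np.array([[[1.2, -0.8, 0.3]]]), (7, 1, 1))
        grid = fg_density(make_traj(frames), np.array([0]), self.spec)
        assert grid.counts.max() == 7
        assert grid.counts.sum() == 7
        assert grid.overflow == 0

    def test_conservation_with_overflow(self):
        rng = np.random.default_rng(4)
        frames = 8.0 * rng.standard_normal((11, 6, 3))  # some points escape
        grid = fg_density(make_traj(frames), np.arange(6), self.spec)
        assert grid.total() == 11 * 6

    def test_frame_order_invariance(self):
        rng = np.random.default_rng(5)
        frames = rng.standard_normal((9, 4, 3))
        g1 = fg_density(make_traj(frames), np.arange(4), self.spec)
        g2 = fg_density(make_traj(frames[::-1]), np.arange(4), self.spec)
        assert np.array_equal(g1.counts, g2.counts)

    def test_uniform_markers_multinomial(self):
        """Uniformly scattered markers fill cells consistently with a
        multinomial over equal cell volumes (chi-square, p > 0.001)."""
        rng = np.random.default_rng(6)
        spec = DensityGridSpec(diameter=4.0, length=4.0, cell=1.0)
        pts = rng.uniform(-2.0, 2.0, size=(40_000, 1, 3))
        grid = fg_density(make_traj(pts), np.array([0]), spec)
        observed = grid.counts.ravel()
        expected = observed.sum() / observed.size
        chi2 = np.sum((observed - expected) ** 2 / expected)
        p = stats.chi2.sf(chi2, df=observed.size - 1)
        assert p > 0.001

    def test_merge_grids_pools_counts(self):
        rng = np.random.default_rng(7)
        frames = rng.standard_normal((5, 3, 3))
        g1 = fg_density(make_traj(frames), np.arange(3), self.spec)
        g2 = fg_density(make_traj(frames + 0.1), np.arange(3), self.spec)
        merged = merge_grids([g1, g2])
        assert merged.total() == g1.total() + g2.total()
        assert merged.n_frames == 10


class TestCompareMetric:
    def mk(self, values, rep=0):
        values = np.asarray(values, float)
        return MetricSeries(values, np.arange(len(values), dtype=float),
                            replicate=rep)

    def test_identical_series_zero_change(self):
        s = self.mk(np.linspace(1, 2, 50))
        out = compare_metric([s], [s])
        assert out["percent_change"] == pytest.approx(0.0)

    def test_half_means_fifty_percent(self):
        wt = self.mk(np.full(100, 4.0))
        mut = self.mk(np.full(100, 2.0))
        assert compare_metric([wt], [mut])["percent_change"] == pytest.approx(50.0)

    def test_pooling_equals_average_of_replicate_means(self):
        # constant series: replicate means are hand-computable
        wt = [self.mk(np.full(10, v), r) for r, v in enumerate((4.0, 5.0, 6.0))]
        mut = [self.mk(np.full(10, v), r) for r, v in enumerate((2.0, 3.0, 4.0))]
        out = compare_metric(wt, mut)
        assert out["wildtype_mean"] == pytest.approx(5.0)
        assert out["mutant_mean"] == pytest.approx(3.0)
        assert out["percent_change"] == pytest.approx(100 * (5 - 3) / 5)
        assert out["wildtype_replicates"] == [4.0, 5.0, 6.0]

    def test_equilibration_fraction_discards_head(self):
        vals = np.concatenate([np.full(20, 100.0), np.full(80, 1.0)])
        out = compare_metric([self.mk(vals)], [self.mk(np.full(100, 1.0))])
        assert out["wildtype_mean"] == pytest.approx(1.0)

    def test_zero_wildtype_mean_rejected(self):
        with pytest.raises(ValueError):
            compare_metric([self.mk(np.zeros(10))], [self.mk(np.ones(10))])


class TestMaxDensityChange:
    spec = DensityGridSpec(diameter=4.0, length=2.0, cell=0.5)

    def mk(self, counts, n_frames=1):
        return DensityGrid(np.asarray(counts, np.int64), 0, n_frames,
                           int(np.sum(counts)), self.spec)

    def test_identical_grids_zero(self):
        c = np.random.default_rng(8).integers(0, 5, self.spec.shape)
        assert max_density_change(self.mk(c), self.mk(c)) == pytest.approx(0.0)

    def test_uniform_scaling_fifty_percent(self):
        c = np.ones(self.spec.shape, dtype=np.int64)
        up = (1.5 * c).astype(np.int64)
        c2 = 2 * c
        up2 = 3 * c
        assert max_density_change(self.mk(c2), self.mk(up2)) == pytest.approx(50.0)

    def test_explicit_small_grids_hand_value(self):
        wt = np.zeros(self.spec.shape, np.int64)
        mut = np.zeros(self.spec.shape, np.int64)
        wt[0, 0, 0], wt[1, 1, 1] = 8, 4
        mut[2, 2, 2], mut[3, 3, 3] = 10, 9
        # per-frame averages over 2 frames: max 4.0 vs 5.0 -> +25%
        out = max_density_change(self.mk(wt, 2), self.mk(mut, 2))
        assert out == pytest.approx(100.0 * (5.0 - 4.0) / 4.0)

    def test_different_specs_rejected(self):
        other = DensityGridSpec(diameter=4.0, length=4.0, cell=0.5)
        g1 = self.mk(np.ones(self.spec.shape, np.int64))
        g2 = DensityGrid(np.ones(other.shape, np.int64), 0, 1, 1, other)
        with pytest.raises(ValueError):
            max_density_change(g1, g2)


class TestRadialAxialProfile:
    def test_ring_of_markers_peaks_at_ring_radius(self):
        spec = DensityGridSpec(diameter=20.0, length=4.0, cell=0.5)
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        ring = np.column_stack(
            [6.0 * np.cos(theta), 6.0 * np.sin(theta), np.zeros_like(theta)]
        )
        grid = fg_density(make_traj(ring[None]), np.arange(64), spec)
        r, z, prof = radial_axial_profile(grid)
        peak_r = r[np.argmax(prof.sum(axis=1))]
        assert abs(peak_r - 6.0) <= spec.cell

    def test_mass_preserved_volume_weighted(self):
        rng = np.random.default_rng(9)
        spec = DensityGridSpec(diameter=10.0, length=4.0, cell=0.5)
        frames = 2.0 * rng.standard_normal((6, 10, 3))
        grid = fg_density(make_traj(frames), np.arange(10), spec)
        _, _, prof = radial_axial_profile(grid)
        cells = cells_per_radial_bin(grid)
        total = np.sum(prof * cells[:, None])
        assert total == pytest.approx(grid.counts.sum() / grid.n_frames)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(10)
        spec = DensityGridSpec(diameter=16.0, length=4.0, cell=0.5)
        pts = rng.uniform(-5, 5, size=(2000, 3))
        pts[:, 2] *= 0.3
        c, s = np.cos(np.pi / 4), np.sin(np.pi / 4)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        g1 = fg_density(make_traj(pts[None]), np.arange(len(pts)), spec)
        g2 = fg_density(make_traj((pts @ rot.T)[None]), np.arange(len(pts)), spec)
        _, _, p1 = radial_axial_profile(g1)
        _, _, p2 = radial_axial_profile(g2)
        # identical up to cell-discretization error
        assert np.abs(p1 - p2).max() <= 0.2 * max(p1.max(), 1e-9) + 0.5


class TestGridSpec:
    def test_uneven_cell_rejected(self):
        with pytest.raises(ValueError):
            DensityGridSpec(diameter=10.0, length=3.3, cell=0.5)

    def test_published_grid_shapes(self):
        ring = DensityGridSpec(diameter=100.0, length=10.0, cell=0.5)
        npc = DensityGridSpec(diameter=100.0, length=140.0, cell=0.5)
        assert ring.shape == (200, 200, 20)
        assert npc.shape == (200, 200, 280)
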