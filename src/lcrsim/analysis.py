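"""Trajectory readouts: end-to-end distance, RMSD, FG density grids, and
wildtype-vs-mutant comparison statistics.

The density grid follows the published convention: FG-motif marker beads
(the F bead of each FG dipeptide) are binned over all sampled frames into
0.5 nm cubic cells filling a cylinder-bounding box — 100 nm diameter with a
10 nm length for a single ring, 140 nm for the whole NPC.  Raw counts are
conserved exactly: markers falling outside the box are tallied in an
overflow counter, so ``counts.sum() + overflow == n_frames * n_markers``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulator import Trajectory


@dataclass(frozen=True)
class DensityGridSpec:
    diameter: float = 100.0          # nm, cylinder/box transverse extent
    length: float = 10.0             # nm along the pore axis (z)
    cell: float = 0.5                # nm cubic cell edge
    center: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        for extent, label in ((self.diameter, "diameter"), (self.length, "length")):
            n = extent / self.cell
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"cell edge must divide {label} evenly")

    @property
    def shape(self) -> tuple:
        n_xy = int(round(self.diameter / self.cell))
        n_z = int(round(self.length / self.cell))
        return (n_xy, n_xy, n_z)

    def edges(self):
        cx, cy, cz = self.center
        half = self.diameter / 2.0
        halfz = self.length / 2.0
        n_xy, _, n_z = self.shape
        return (
            np.linspace(cx - half, cx + half, n_xy + 1),
            np.linspace(cy - half, cy + half, n_xy + 1),
            np.linspace(cz - halfz, cz + halfz, n_z + 1),
        )


@dataclass
class DensityGrid:
    counts: np.ndarray               # (nx, ny, nz) raw occupancy counts
    overflow: int
    n_frames: int
    n_markers: int
    spec: DensityGridSpec

    @property
    def per_frame(self) -> np.ndarray:
        """Per-frame-averaged occupancy per cell."""
        return self.counts / max(self.n_frames, 1)

    def total(self) -> int:
        return int(self.counts.sum()) + self.overflow


@dataclass
class MetricSeries:
    """Per-frame scalar readout (nm) for a named bead subset."""

    values: np.ndarray
    times: np.ndarray
    label: str = ""
    replicate: int = 0


def end_to_end(traj: Trajectory, bead_range: tuple, label: str = "",
               replicate: int = 0, chain_id: np.ndarray | None = None
               ) -> MetricSeries:
    """Per-frame distance between the first and last bead of ``bead_range``
    (half-open bead indices).  The range must lie within a single chain."""
    start, stop = bead_range
    if stop - start < 1 or start < 0 or stop > traj.frames.shape[1]:
        raise ValueError(f"invalid bead range {bead_range}")
    if chain_id is not None and chain_id[start] != chain_id[stop - 1]:
        raise ValueError("bead range spans more than one chain")
    d = np.linalg.norm(traj.frames[:, stop - 1] - traj.frames[:, start], axis=1)
    return MetricSeries(d, traj.times.copy(), label, replicate)


def _kabsch_rmsd(frames: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Minimum RMSD of each frame against ``ref`` after optimal rigid-body
    superposition (Kabsch)."""
    ref_c = ref - ref.mean(axis=0)
    out = np.empty(len(frames))
    for f, frame in enumerate(frames):
        x = frame - frame.mean(axis=0)
        h = x.T @ ref_c
        u, s, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(u @ vt))
        rot = u @ np.diag([1.0, 1.0, d]) @ vt
        out[f] = np.sqrt(np.mean(np.sum((x @ rot - ref_c) ** 2, axis=1)))
    return out


def rmsd(traj: Trajectory, reference_frame: int, bead_range: tuple,
         align: bool = True, label: str = "", replicate: int = 0
         ) -> MetricSeries:
    """Per-frame RMSD of a bead subset from a reference frame.

    With ``align`` (the default, matching the usual visualization-tool
    convention) each frame is first optimally superposed on the reference;
    without it the raw deviation is reported.
    """
    start, stop = bead_range
    sub = traj.frames[:, start:stop]
    ref = traj.frames[reference_frame, start:stop]
    if align:
        vals = _kabsch_rmsd(sub, ref)
    else:
        vals = np.sqrt(np.mean(np.sum((sub - ref) ** 2, axis=2), axis=1))
    return MetricSeries(vals, traj.times.copy(), label, replicate)


def fg_density(traj: Trajectory, fg_markers: np.ndarray,
               spec: DensityGridSpec | None = None) -> DensityGrid:
    """Accumulate FG-marker occupancy counts over all frames of a trajectory."""
    spec = spec or DensityGridSpec()
    markers = np.asarray(fg_markers, dtype=np.int64)
    pts = traj.frames[:, markers].reshape(-1, 3)
    counts, _ = np.histogramdd(pts, bins=spec.edges())
    counts = counts.astype(np.int64)
    total = traj.n_frames * len(markers)
    return DensityGrid(
        counts=counts,
        overflow=total - int(counts.sum()),
        n_frames=traj.n_frames,
        n_markers=len(markers),
        spec=spec,
    )


def merge_grids(grids: list[DensityGrid]) -> DensityGrid:
    """Pool replicate grids (same spec) into one."""
    spec = grids[0].spec
    if any(g.spec != spec for g in grids):
        raise ValueError("grids have different specs")
    return DensityGrid(
        counts=np.sum([g.counts for g in grids], axis=0),
        overflow=sum(g.overflow for g in grids),
        n_frames=sum(g.n_frames for g in grids),
        n_markers=grids[0].n_markers,
        spec=spec,
    )


def compare_metric(
    wildtype: list[MetricSeries],
    mutant: list[MetricSeries],
    equilibration_fraction: float = 0.2,
) -> dict:
    """Percent change of a metric between variants, with replicate spread.

    The first ``equilibration_fraction`` of every series is discarded; each
    replicate contributes its time-average; the percent change is
    ``100 * (mean_wt - mean_mut) / mean_wt`` on the averages of replicate
    means, with the uncertainty propagated from the standard errors across
    replicates.
    """
    def replicate_means(series):
        out = []
        for s in series:
            cut = int(len(s.values) * equilibration_fraction)
            out.append(float(np.mean(s.values[cut:])))
        return np.array(out)

    wt, mut = replicate_means(wildtype), replicate_means(mutant)
    m_wt, m_mut = wt.mean(), mut.mean()
    if m_wt == 0:
        raise ValueError("zero wildtype mean")
    se_wt = wt.std(ddof=1) / np.sqrt(len(wt)) if len(wt) > 1 else 0.0
    se_mut = mut.std(ddof=1) / np.sqrt(len(mut)) if len(mut) > 1 else 0.0
    pct = 100.0 * (m_wt - m_mut) / m_wt
    # d(pct)/d(m_wt) = 100*m_mut/m_wt^2 ; d(pct)/d(m_mut) = -100/m_wt
    sigma = np.sqrt(
        (100.0 * m_mut / m_wt**2 * se_wt) ** 2 + (100.0 / m_wt * se_mut) ** 2
    )
    return {
        "percent_change": pct,
        "uncertainty": float(sigma),
        "wildtype_mean": float(m_wt),
        "mutant_mean": float(m_mut),
        "wildtype_se": float(se_wt),
        "mutant_se": float(se_mut),
        "wildtype_replicates": wt.tolist(),
        "mutant_replicates": mut.tolist(),
    }


def max_density_change(wildtype: DensityGrid, mutant: DensityGrid,
                       smooth_sigma: float = 0.0) -> float:
    """Percent change of the peak per-frame-averaged FG density,
    ``100 * (max_mut - max_wt) / max_wt``.

    Optional Gaussian smoothing (in cells) is off by default: raw
    single-cell maxima are noisy, and the published comparisons are made on
    the raw grid.
    """
    if wildtype.spec != mutant.spec:
        raise ValueError("grids have different specs")
    wt, mut = wildtype.per_frame, mutant.per_frame
    if smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        wt = gaussian_filter(wt, smooth_sigma)
        mut = gaussian_filter(mut, smooth_sigma)
    max_wt = wt.max()
    if max_wt == 0:
        raise ValueError("empty wildtype grid")
    return float(100.0 * (mut.max() - max_wt) / max_wt)


def radial_axial_profile(grid: DensityGrid):
    """Azimuthally averaged (r, z) density map of the 3-D grid.

    Returns ``(r_centers, z_centers, profile)`` where ``profile[ir, iz]`` is
    the mean per-frame count of the cells whose center falls in radial bin
    ``ir`` at axial slab ``iz``.  Volume-weighting by the cell count per bin
    recovers the total mass.
    """
    spec = grid.spec
    ex, ey, ez = spec.edges()
    xc = 0.5 * (ex[:-1] + ex[1:]) - spec.center[0]
    yc = 0.5 * (ey[:-1] + ey[1:]) - spec.center[1]
    zc = 0.5 * (ez[:-1] + ez[1:])
    r = np.sqrt(xc[:, None] ** 2 + yc[None, :] ** 2)
    n_r = int(np.ceil((spec.diameter / 2.0) / spec.cell)) + 1
    ir = np.minimum((r / spec.cell).astype(int), n_r - 1)
    dens = grid.per_frame
    profile = np.zeros((n_r, len(zc)))
    cells = np.zeros(n_r, dtype=np.int64)
    np.add.at(cells, ir.ravel(), 1)
    for iz in range(len(zc)):
        np.add.at(profile[:, iz], ir.ravel(), dens[:, :, iz].ravel())
    nonzero = cells > 0
    profile[nonzero] /= cells[nonzero, None]
    r_centers = (np.arange(n_r) + 0.5) * spec.cell
    return r_centers, zc, profile


def cells_per_radial_bin(grid: DensityGrid) -> np.ndarray:
    """Number of (x, y) cells pooled into each radial bin of the profile."""
    spec = grid.spec
    ex, ey, _ = spec.edges()
    xc = 0.5 * (ex[:-1] + ex[1:]) - spec.center[0]
    yc = 0.5 * (ey[:-1] + ey[1:]) - spec.center[1]
    r = np.sqrt(xc[:, None] ** 2 + yc[None, :] ** 2)
    n_r = int(np.ceil((spec.diameter / 2.0) / spec.cell)) + 1
    ir = np.minimum((r / spec.cell).astype(int), n_r - 1)
    cells = np.zeros(n_r, dtype=np.int64)
    np.add.at(cells, ir.ravel(), 1)
    return cells


def plot_profile(grid: DensityGrid, ax=None, **imshow_kw):
    """Basic (r, z) heatmap of a density grid (doughnut cross-section)."""
    import matplotlib.pyplot as plt

    r, z, prof = radial_axial_profile(grid)
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(
        prof.T, origin="lower", aspect="auto",
        extent=[r[0], r[-1], z[0], z[-1]], **imshow_kw,
    )
    ax.set_xlabel("r (nm)")
    ax.set_ylabel("z (nm)")
    return im
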