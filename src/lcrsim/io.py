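"""Flat-file export: density grids (OpenDX, CSV), metric time series (TSV),
geometry/config round-trips."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import DensityGrid, MetricSeries
from .geometry import NPCGeometry


def export_grid_dx(grid: DensityGrid, path) -> None:
    """OpenDX volumetric export of the per-frame-averaged density (the
    format VMD and Chimera read for isosurface rendering)."""
    spec = grid.spec
    nx, ny, nz = spec.shape
    ex, ey, ez = spec.edges()
    origin = (ex[0] + spec.cell / 2, ey[0] + spec.cell / 2, ez[0] + spec.cell / 2)
    data = grid.per_frame.ravel(order="C")
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {origin[0]:.4f} {origin[1]:.4f} {origin[2]:.4f}\n")
        fh.write(f"delta {spec.cell:.4f} 0 0\n")
        fh.write(f"delta 0 {spec.cell:.4f} 0\n")
        fh.write(f"delta 0 0 {spec.cell:.4f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {data.size} data follows\n"
        )
        for i in range(0, data.size, 3):
            fh.write(" ".join(f"{v:.6g}" for v in data[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


def export_grid_csv(grid: DensityGrid, path, nonzero_only: bool = True) -> None:
    """Flat (x, y, z, count) table of the raw counts; by default only
    occupied cells are written (the full grid is mostly empty)."""
    spec = grid.spec
    ex, ey, ez = spec.edges()
    xc = 0.5 * (ex[:-1] + ex[1:])
    yc = 0.5 * (ey[:-1] + ey[1:])
    zc = 0.5 * (ez[:-1] + ez[1:])
    if nonzero_only:
        ix, iy, iz = np.nonzero(grid.counts)
    else:
        ix, iy, iz = np.indices(spec.shape).reshape(3, -1)
    df = pd.DataFrame(
        {
            "x": xc[ix],
            "y": yc[iy],
            "z": zc[iz],
            "count": grid.counts[ix, iy, iz],
        }
    )
    df.to_csv(path, index=False)


def metrics_tsv(series: list[MetricSeries], path) -> None:
    """Long-format TSV of metric time series (label, replicate, time, value)."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "label": s.label,
                    "replicate": s.replicate,
                    "time_ps": s.times,
                    "value_nm": s.values,
                }
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def geometry_to_yaml(geom: NPCGeometry, path) -> None:
    doc = {
        "scaffold": {
            "r_waist": geom.scaffold.r_waist,
            "r_end": geom.scaffold.r_end,
            "half_length": geom.scaffold.half_length,
            "contact": geom.scaffold.contact,
            "k_wall": geom.scaffold.k_wall,
            "blobs": np.asarray(geom.scaffold.blobs).tolist(),
        },
        "anchors": [
            {"nup": s.nup, "radius": s.radius, "z": s.z, "terminus": s.terminus}
            for s in geom.sites
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def save_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float))
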