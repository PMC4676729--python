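"""End-to-end experiment orchestration.

One configuration drives the whole comparison: scan the input sequence for
its largest positive like-charge region, build the charged-to-Ala mutant
(or a control mutation at explicit positions), simulate both variants for
the requested number of replicates, measure end-to-end distance and RMSD of
the whole chain and of the LCR, accumulate FG density grids (ring/NPC), and
write a comparison report plus a manifest with seeds and hashes.
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import analysis, io
from .forcefield import ForceFieldParams
from .geometry import RingSpec, build_ring, build_single
from .sequences import (
    NupSequence,
    largest_positive_lcr,
    mutate_charged_to_ala,
    mutate_positions,
    read_fasta,
)
from .simulator import SimulationParams, Trajectory, run_protocol, system_hash
from .synthetic import SyntheticNupSpec, generate_nup


@dataclass
class ExperimentConfig:
    protocol: str = "individual"         # individual | ring
    replicates: int = 3
    scale: float = 1.0
    seed: int = 0
    outdir: str = "lcr_experiment"
    # input: either a FASTA path + nup name, or a synthetic spec
    fasta: str | None = None
    nup: str | None = None
    synthetic: SyntheticNupSpec | None = None
    # mutation: the detected LCR by default, or explicit control positions
    control_positions: tuple | None = None
    ring_diameter: float = 30.0
    sim: SimulationParams = field(default_factory=SimulationParams)
    ff: ForceFieldParams = field(default_factory=ForceFieldParams)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        kwargs = {}
        for key in ("protocol", "replicates", "scale", "seed", "outdir",
                    "fasta", "nup", "ring_diameter"):
            if key in doc:
                kwargs[key] = doc[key]
        if "control_positions" in doc:
            kwargs["control_positions"] = tuple(doc["control_positions"])
        if "synthetic" in doc:
            syn = dict(doc["synthetic"])
            if "lcr_span" in syn:
                syn["lcr_span"] = tuple(syn["lcr_span"])
            kwargs["synthetic"] = SyntheticNupSpec(**syn)
        if "sim" in doc:
            kwargs["sim"] = SimulationParams(**doc["sim"])
        if "ff" in doc:
            kwargs["ff"] = ForceFieldParams(**doc["ff"])
        cfg = cls(**kwargs)
        if cfg.fasta is not None and not Path(cfg.fasta).exists():
            raise FileNotFoundError(cfg.fasta)
        if cfg.replicates < 1:
            raise ValueError("replicates must be >= 1")
        return cfg


def _load_sequence(config: ExperimentConfig) -> NupSequence:
    if config.fasta is not None:
        seqs = {s.name: s for s in read_fasta(config.fasta)}
        if config.nup is None:
            if len(seqs) != 1:
                raise ValueError("multi-record FASTA needs an explicit nup name")
            return next(iter(seqs.values()))
        return seqs[config.nup]
    if config.synthetic is not None:
        seq, _ = generate_nup(config.synthetic)
        return seq
    raise ValueError("config needs either a FASTA input or a synthetic spec")


def _traj_hash(traj: Trajectory) -> str:
    return hashlib.sha256(
        np.ascontiguousarray(traj.frames).tobytes()
    ).hexdigest()[:16]


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full wildtype-vs-mutant comparison described by ``config``.

    Results land under ``config.outdir`` (one subdirectory per variant and
    replicate, a top-level ``comparison.json`` and ``manifest.json``).  On a
    stage failure the partial results stay on disk and the manifest records
    the failure point before the exception propagates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            "protocol": config.protocol,
            "replicates": config.replicates,
            "scale": config.scale,
            "seed": config.seed,
        },
        "stages": [],
    }

    def record(stage, **info):
        manifest["stages"].append(
            {"stage": stage, "wall_time": time.time(), **info}
        )
        io.save_report(manifest, outdir / "manifest.json")

    try:
        wt = _load_sequence(config)
        region = largest_positive_lcr(wt)
        if config.control_positions:
            mut = mutate_positions(wt, config.control_positions, "A")
        else:
            if region is None:
                raise ValueError(f"{wt.name} has no positive like-charge region")
            mut = mutate_charged_to_ala(wt, region)
        lcr_range = (region.start - 1, region.end) if region else (0, len(wt))
        record("scan", nup=wt.name,
               lcr=None if region is None else
               {"start": region.start, "end": region.end,
                "n_charges": region.n_charges})

        results: dict = {}
        for variant, seq in (("wildtype", wt), ("mutant", mut)):
            series: dict[str, list] = {
                "e2e_whole": [], "e2e_lcr": [], "rmsd_whole": [], "rmsd_lcr": [],
            }
            grids = []
            for rep in range(config.replicates):
                rep_dir = outdir / variant / f"rep{rep}"
                rep_dir.mkdir(parents=True, exist_ok=True)
                seed = (config.seed + 1009 * rep
                        + (0 if variant == "wildtype" else 499979)) % (2**31 - 1)
                if config.protocol == "ring":
                    spec = RingSpec(seq.name, config.ring_diameter)
                    system = build_ring(spec, seq, config.ff, seed=seed)
                else:
                    system = build_single(seq, config.ff, seed=seed)
                sim = SimulationParams(
                    **{**config.sim.__dict__, "seed": seed}
                )
                traj = run_protocol(system, config.ff, sim,
                                    protocol=config.protocol,
                                    scale=config.scale)
                traj.save_hdf5(rep_dir / "trajectory.h5")
                chain0 = (0, len(seq))
                series["e2e_whole"].append(
                    analysis.end_to_end(traj, chain0, "e2e_whole", rep))
                series["e2e_lcr"].append(
                    analysis.end_to_end(traj, lcr_range, "e2e_lcr", rep))
                series["rmsd_whole"].append(
                    analysis.rmsd(traj, 0, chain0, label="rmsd_whole",
                                  replicate=rep))
                series["rmsd_lcr"].append(
                    analysis.rmsd(traj, 0, lcr_range, label="rmsd_lcr",
                                  replicate=rep))
                if config.protocol == "ring":
                    spec3d = analysis.DensityGridSpec(length=10.0)
                    grids.append(
                        analysis.fg_density(traj, system.fg_markers, spec3d))
                io.metrics_tsv(
                    [series[k][-1] for k in series], rep_dir / "metrics.tsv")
                record(f"{variant}/rep{rep}", seed=seed,
                       system_hash=system_hash(system),
                       trajectory_hash=_traj_hash(traj))
            results[variant] = {"series": series, "grids": grids}

        comparison = {
            metric: analysis.compare_metric(
                results["wildtype"]["series"][metric],
                results["mutant"]["series"][metric],
            )
            for metric in ("e2e_whole", "e2e_lcr", "rmsd_whole", "rmsd_lcr")
        }
        if results["wildtype"]["grids"]:
            wt_grid = analysis.merge_grids(results["wildtype"]["grids"])
            mut_grid = analysis.merge_grids(results["mutant"]["grids"])
            comparison["max_density_change_pct"] = analysis.max_density_change(
                wt_grid, mut_grid)
            io.export_grid_dx(wt_grid, outdir / "wildtype" / "fg_density.dx")
            io.export_grid_dx(mut_grid, outdir / "mutant" / "fg_density.dx")
        io.save_report(comparison, outdir / "comparison.json")
        record("comparison", ok=True)
        return {"comparison": comparison, "manifest": manifest,
                "results": results}
    except Exception as exc:
        record("FAILED", error=str(exc), trace=traceback.format_exc())
        raise


def load_report(outdir) -> dict:
    return json.loads((Path(outdir) / "comparison.json").read_text())
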