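# lcrsim

Coarse-grained simulation and sequence analysis of **like charge regions
(LCRs)** in FG nucleoporins — the intrinsically disordered, FG-repeat-rich
proteins that form the selective barrier of the nuclear pore complex (NPC).

An LCR is a maximal stretch of sequence whose charged residues all carry
the same sign.  The largest positively charged LCR of each FG Nup overlaps
its FG-rich domain, and neutralizing its charges (charged-to-Ala scanning)
collapses that domain: the end-to-end distance of the LCR drops sharply,
its dynamics slow down, and in multi-chain arrangements the FG motifs
aggregate into dense clumps instead of covering the pore.  `lcrsim` is
built for exactly this comparison: detect the LCR, build the mutant, run
both variants through the same Langevin protocol, and quantify the
difference.

The package provides, as composable library modules with a thin `lcr` CLI:

* **sequences** — FASTA I/O, per-residue charge annotation, maximal
  same-sign region detection, FG-motif scanning, charged-to-Ala and
  positional mutagenesis;
* **forcefield / simulator** — a one-bead-per-residue model (120 Da,
  0.38 nm bonds; bending/torsion; WCA excluded volume with a
  hydrophobicity-scaled attractive tail cut at 2.5 nm; Debye–Hückel
  electrostatics with κ = 1 nm⁻¹ cut at 5 nm) integrated by BAOAB Langevin
  dynamics (γ = 50 ps⁻¹, Δt = 0.02 ps) with numba-compiled kernels,
  staged clash minimization, and seeded bit-reproducibility;
* **geometry** — isolated chains, eightfold rings tethered at the NPC
  diameter of the Nup's anchoring point, and a whole-NPC build on a rigid
  hourglass scaffold (excluded volume only, optional blobs);
* **analysis** — end-to-end distance, Kabsch-aligned RMSD, 3-D FG-density
  grids on 0.5 nm cells in a bounding cylinder (100 nm × 10 nm for rings,
  × 140 nm for the NPC) with exact count conservation, azimuthal (r, z)
  profiles, and wildtype-vs-mutant percent changes with replicate errors;
* **synthetic** — seeded generators of FG-Nup-like sequences with planted
  LCRs, so every stage is testable without external downloads.

See `docs/methods.md` for the model, parameters, and calibration.

## Worked example

```python
import numpy as np
from lcrsim import (SyntheticNupSpec, generate_nup, largest_positive_lcr,
                    mutate_charged_to_ala, build_single, SimulationParams,
                    run_langevin, end_to_end, compare_metric)

# a 120-residue FG-Nup-like sequence with a planted 30-residue, 6-Lys LCR
wt, info = generate_nup(SyntheticNupSpec(length=120, lcr_span=(31, 60),
                                         lcr_n_positive=6, seed=20))
region = largest_positive_lcr(wt)
print(region.start, region.end, region.n_charges)   # -> 31 60 6

mut = mutate_charged_to_ala(wt, region)
lcr = (region.start - 1, region.end)

series = {}
for name, seq in [("wildtype", wt), ("mutant", mut)]:
    reps = []
    for rep in range(3):
        system = build_single(seq, seed=101 + rep)
        params = SimulationParams(friction=1.0, n_steps=400_000,
                                  sampling_interval=500, seed=7 + 13 * rep)
        traj = run_langevin(system, params=params)
        reps.append(end_to_end(traj, lcr, "e2e_lcr", rep))
    series[name] = reps

out = compare_metric(series["wildtype"], series["mutant"],
                     equilibration_fraction=1/3)
print(f"{out['wildtype_mean']:.2f} -> {out['mutant_mean']:.2f} nm "
      f"({out['percent_change']:.0f}% reduction)")
```

This prints (a few minutes on one CPU):

```
31 60 6
3.95 -> 2.38 nm (40% reduction)
```

meaning the six lysines of the planted LCR hold the region open: remove
their charges and the FG-rich stretch collapses to about two thirds of its
wildtype size — the same directional effect, at comparable magnitude, that drives
the redistribution of FG density in ring and whole-NPC simulations.
(The run above samples at reduced friction; equilibrium averages do not
depend on the friction coefficient.)

The same comparison runs end-to-end from a config file:

```bash
lcr scan nups.fasta                      # detect LCRs
lcr mutate nups.fasta --nup Nsp1 --lcr   # write the charged-to-Ala mutant
lcr run experiment.yaml                  # full wildtype-vs-mutant pipeline
```

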