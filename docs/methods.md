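# Methods

`lcrsim` models how *like charge regions* (LCRs) — contiguous sequence
stretches of FG nucleoporins whose charged residues all share one sign —
control the size and dynamics of the FG-repeat domains that form the
nuclear pore complex (NPC) permeability barrier.  The package covers the
whole computational chain: LCR detection and charged-to-Ala mutagenesis at
the sequence level, a one-bead-per-residue coarse-grained Langevin model of
the disordered domains (isolated, in eightfold rings, or tethered inside a
rigid hourglass scaffold), and the readouts used to compare wildtype and
charge-neutralized variants (end-to-end distance, RMSD, 3-D FG-density
grids).

## Sequence model

A disordered domain is a string of one-letter codes; positions are 1-based
inclusive throughout.  Charges follow the physiological-pH side-chain
convention: K, R → +1; D, E → −1; histidine neutral; termini uncharged
because the domains are excised from longer proteins.  The convention is a
plain dict and can be replaced (e.g. protonated His).

An LCR of sign *s* is defined as a **maximal** interval containing at least
`min_charges` (default 2) charges of sign *s* and no charge of sign −*s*;
it therefore extends to the residues adjacent to the nearest opposite-sign
charges or to the sequence ends.  "Largest positive LCR" means the longest
residue span (ties break toward the smaller start); counting charges
instead of span is available via `size_metric="charges"` since the
upstream bioinformatics convention is not restated in the source
literature.  Charged-to-Ala scanning replaces every charged residue inside
a region with alanine, preserving length and neutralizing the region.

FG motifs are exact FG dipeptides; an FxFG or GLFG motif is counted through
its constituent FG.  The F bead of each FG is the marker used in density
analysis.

## Coarse-grained force field

One bead per residue, 120 Da, bonded at 0.38 nm.  Units: nm, ps, kJ/mol,
elementary charge; kB = 0.008314 kJ/mol/K.  Terms:

* **Bonds** — stiff harmonic about 0.38 nm (k = 8000 kJ/mol/nm², a
  constraint surrogate with ~2% RMS fluctuation at 300 K).
* **Bending** — harmonic in the angle (k = 4 kJ/mol/rad², θ₀ = 120°), or a
  user-supplied tabulated potential on a uniform grid (evaluated by cubic
  Hermite interpolation so analytic forces are the exact derivative of the
  interpolant).  Tables allow Boltzmann-inverted statistics from atomistic
  simulations to be dropped in.
* **Torsions** — cosine series Σₙ kₙ(1 + cos(nφ − φₙ)), default a single
  weak trans-favoring term (k = 0.5 kJ/mol); tabulated alternative as for
  bending.  The dihedral angle is undefined at collinear triplets and its
  gradient diverges there; because the soft bending potential makes
  near-collinear states thermally accessible, the torsion energy is tapered
  smoothly to zero (cosine switch on both flanking bending angles between
  2.6 and 3.0 rad), with the taper gradient included analytically.  Without
  the taper, force spikes at near-collinear triplets slowly pump energy
  into weakly damped (low-friction) runs.
* **Excluded volume + hydrophobicity** — a two-part Lennard-Jones: WCA
  repulsion (σ = 0.6 nm, ε_rep = 1 kJ/mol) plus an attractive LJ tail of
  depth ε_hp(i,j) = ε_max · g(hᵢ, hⱼ), truncated and shifted to zero at
  2.5 nm.  g is the geometric mean by default (arithmetic available).
* **Electrostatics** — Debye–Hückel, U = (f/ε_r)·qᵢqⱼ·exp(−κr)/r with
  κ = 1.0 nm⁻¹ and ε_r = 80, truncated and shifted at 5.0 nm.
* **Scaffold** — harmonic excluded-volume penalty against the hourglass
  wall (parabolic radius profile) and optional blob spheres; excluded
  volume only, no attraction.

Truncate-and-shift keeps every energy continuous at its cutoff; forces keep
the unshifted derivative (the standard discontinuity of plain cutoffs).
Directly bonded pairs (depth 1) are excluded from nonbonded terms; 1-3 and
1-4 interactions are governed jointly by bending/torsion and the WCA core.

### Hydrophobicity scale and calibration

The default per-residue hydrophobicity is the positive part of the
Kyte–Doolittle index, h = max(KD, 0)/4.5, so polar and charged residues are
non-attractive and the S/T/N/Q-rich spacers of FG Nups behave as a
good-solvent background, while F/L/I/V/A contacts provide cohesion.  The
two free knobs — the combination rule g and ε_max — were calibrated on the
package's synthetic Nup (120 residues, a planted 30-residue LCR carrying 6
lysines): ε_max was chosen so that the charged-to-Ala mutation reduces the
equilibrium LCR end-to-end distance by ~35–50%, the magnitude reported for
yeast FG Nups in this class of model; the acceptance script recomputes this
quantity under the default **ε_max = 7.0 kJ/mol, geometric rule**.  The
reduction grows with ε_max through the coil–globule transition region, and
collapses of both variants (no contrast) occur when ε_max is pushed well
beyond it.  A normalized
(unclipped) KD scale is a poor default here: it makes the polar background
itself sticky, both variants collapse, and the charge effect disappears.
Scales are plain data and can be replaced wholesale.

## Systems and initial structures

Chains start as self-avoiding random walks with exact 0.38 nm bonds, no two
beads (≥2 bonds apart) closer than σ, and consecutive bond directions
within 75° (backtracking when stuck).  Isolated Nups are free; ring systems
place eight copies with their anchor bead (C-terminal by default,
configurable per Nup) frozen on a circle of the configured ring diameter at
45° spacing, chains growing inward; the whole-NPC build tethers every
configured Nup (×8 copies) on the hourglass wall.  Anchoring uses the
infinite-mass convention (inverse mass 0), so tethered beads are exactly
immobile.  The mutant NPC variant applies the LCR mutation to the seven
Nups whose largest LCR is positive (Nsp1, Nup42, Nup49, Nup57, Nup100,
Nup116, Nup145N) and leaves Nup1, Nup2, Nup159, Nup60 wildtype.

The shipped NPC geometry (hourglass waist 20 nm, end radius 35 nm, channel
length 35 nm, anchor axial positions per Nup) is a documented placeholder
with realistic overall dimensions, not measured coordinates; quantitative
whole-NPC work must supply a geometry file.

## Dynamics

Langevin dynamics uses BAOAB splitting, friction γ = 50 ps⁻¹ (the collision
frequency of water) and timestep 0.02 ps.  BAOAB reduces to velocity Verlet
at γ = 0 (verified: bounded shadow-energy oscillation, no drift) and
remains accurate for configurational averages at high friction.  Thermal
noise is pre-drawn per block from a seeded `numpy.random.Generator`, so a
given (system, parameters, seed) is bit-reproducible on one platform.

Nonbonded interactions use two Verlet pair lists rebuilt on a half-skin
displacement criterion (skin 0.3 nm): one at the van der Waals cutoff over
all beads, one at the Coulomb cutoff over charged beads only — charged
residues are a minority in FG Nups, so the long-range list stays small.
Pair search is brute-force O(N²) inside the compiled kernel, which is the
right trade-off at the ≤10³-bead scale this package targets.

Minimization is a three-stage displacement-capped steepest descent (stage
1: bonds + excluded volume + scaffold; stage 2: + bending/torsion; stage 3:
full potential), each stage monotone in energy with an adaptive step.

Protocols mirror the three experiment levels: *individual* — a single
100 ns run; *ring*/*npc* — minimization, a 100 ns relaxation run at reduced
temperature (T/3; the relaxation stage of the original protocol is
ambiguous between minimization and low-temperature dynamics, so the factor
is configurable), then 900 ns of production.  One scale factor multiplies
every duration, so the identical protocol runs at desk scale; a replicate
index offsets only the integration seed (replicates share the built
system).  Reported times are nominal coarse-grained times; no speed-up
factor to physical time is applied.

## Readouts

* **End-to-end distance** — per frame, between the first and last bead of a
  range (whole chain or the LCR sub-range of each copy).
* **RMSD** — against a reference frame, by default after optimal rigid-body
  (Kabsch) superposition, matching common visualization-tool practice; raw
  deviation available.  Cross-checked against mdtraj in the test suite.
* **FG density grid** — F-bead markers binned over all frames into 0.5 nm
  cubic cells filling the box of a bounding cylinder: 100 nm diameter and
  10 nm length for a ring, 140 nm length for the NPC.  Counts are conserved
  exactly (out-of-box markers go to an overflow tally).  Grids export to
  OpenDX and CSV; an azimuthally averaged (r, z) profile provides the
  doughnut-shaped cross-sections.
* **Comparisons** — replicate series are averaged after discarding the
  first 20% of each (equilibration; the averaging window of the original
  figures is unspecified), the percent change is computed on means of
  replicate means, and the uncertainty propagates the standard errors
  across replicates.  Peak-density changes are computed on raw
  per-frame-averaged grids; Gaussian smoothing is opt-in because raw
  single-cell maxima are noisy.

## What the synthetic generator does and does not emulate

`generate_nup` plants a known LCR (exact span, K-count, no internal
negatives, opposite charges pinned at the flanks so the detected maximal
region equals the plan), places FG dipeptides at a target density enriched
2× inside the LCR (the observed co-localization of LCRs with FG-rich
regions), and fills the background with a polar S/T/N/Q-skewed composition
carrying mixed charges (same-sign runs broken so no background region
outgrows the planted one).  It does **not** reproduce any real Nup
residue-for-residue, nor FxFG/GLFG spacing statistics, nor the two-domain
(collapsed coil vs stalk) architecture of the long Nups.  Passing tests on
synthetic sequences therefore demonstrate that the machinery — detection,
mutagenesis, simulation, readouts — behaves correctly and reproduces the
directional physics, not that the yeast-specific published percentages are
recovered; those require the external yeast disordered-domain sequences
and microsecond-scale runs.

## Problem sizes used in the shipped tests

The test suite and the acceptance script run desk-scale versions of each
experiment, chosen as the smallest systems that exercise the full code
paths: gradient checks on an 18-residue chain; the thermostat check on a
50-mer over 10⁶ steps; the chain-statistics check on a 50-mer sampled by
two 8×10⁶-step Langevin runs against a 6×10⁵-move Metropolis sampler of
the identical potential (that check uses light beads and soft bonds, which
shorten the relaxation time and lower the bond frequency without entering
the equilibrium distribution being compared); the directional mutation
effect on an eightfold ring of a 40-residue Nup (30-residue LCR, 6 Lys)
through the ring protocol at scale 0.01 with 3 replicates per variant; and
the equilibrium wildtype-vs-mutant contrast on the 120-residue synthetic
Nup at reduced friction (equilibrium averages are friction-independent,
and the LCR relaxation time at γ = 50 ps⁻¹, roughly 10 ns, would otherwise
dominate desk-scale runs).

## Known limitations

* The force-field functional forms are standard choices with every constant
  exposed; they are not a refit of any published parameterization, though
  tabulated bending/torsion input can reproduce one.
* Cutoff forces are discontinuous at the cutoffs (truncate-and-shift).
* The scaffold is rigid and purely repulsive; no cargo or transporter
  species exist in the model.
* Kinetic-energy averages carry the O((ωΔt)²) discretization bias of BAOAB
  (≈0.5% at the default bond stiffness and timestep).
* The self-avoiding-walk initializer can fail in extremely crowded builds;
  it backtracks but ultimately raises rather than emitting overlapping
  structures.
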