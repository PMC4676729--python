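"""Synthetic FG-Nup-like sequences with planted like-charge regions.

Real FG-Nup disordered domains are FG-dipeptide-rich, polar (S/T/N/Q-heavy),
and carry a contiguous stretch whose charged residues are all positive — the
like charge region (LCR) that co-localizes with the FG-rich domain.  The
generator emulates exactly that: a polar background, FG dipeptides at a
target density (enriched inside the planted LCR to mimic the co-localization),
a prescribed number of lysines inside the LCR with no negative charge there,
and mixed charges outside.  Opposite-sign charges are pinned to the residues
flanking the planted span so the detected maximal region equals the plan;
the generator verifies this with the detector and redraws on the rare miss.

Everything is seeded and reproducible; these sequences stand in for the
yeast Nups in tests, not as mimics of any particular real sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .geometry import AnchorSite, NPCGeometry, RingSpec
from .sequences import (
    NupSequence,
    find_fg_motifs,
    largest_positive_lcr,
    mutate_charged_to_ala,
)
from .system import Scaffold

#: Polar-rich background composition typical of FG-Nup spacers.
BACKGROUND = {
    "S": 0.24, "T": 0.16, "N": 0.15, "Q": 0.14,
    "A": 0.13, "G": 0.12, "P": 0.06,
}


@dataclass(frozen=True)
class SyntheticNupSpec:
    length: int = 120
    fg_fraction: float = 0.08            # FG dipeptides per residue
    lcr_span: tuple = (31, 70)           # 1-based inclusive
    lcr_n_positive: int = 4
    background_charge_density: float = 0.10   # charged residues per residue
    background_positive_fraction: float = 0.5
    lcr_fg_enrichment: float = 2.0       # FG density multiplier inside LCR
    seed: int = 0

    def validate(self) -> None:
        s, e = self.lcr_span
        if not (1 <= s <= e <= self.length):
            raise ValueError(f"lcr_span {self.lcr_span} outside 1-{self.length}")
        span = e - s + 1
        if self.lcr_n_positive > span // 2:
            raise ValueError("lcr_n_positive too large for the span")
        load = 2 * self.fg_fraction + self.background_charge_density
        if load > 0.8:
            raise ValueError(
                f"fg_fraction + charge density too high (residue load {load:.2f})"
            )
        if self.fg_fraction < 0 or self.background_charge_density < 0:
            raise ValueError("fractions must be non-negative")


def generate_nup(spec: SyntheticNupSpec, name: str = "synthFG"):
    """Generate one sequence satisfying ``spec``.

    Returns ``(NupSequence, report)``; the report carries the planted truth
    (LCR span, charge positions, FG positions) and the realized composition.
    The detector is run post hoc: the largest positive LCR of the output
    equals the planted span under default settings, or the draw is repeated.
    """
    spec.validate()
    L = spec.length
    s0, e0 = spec.lcr_span[0] - 1, spec.lcr_span[1] - 1  # 0-based inclusive
    aas = list(BACKGROUND)
    probs = np.array(list(BACKGROUND.values()))
    probs = probs / probs.sum()

    for attempt in range(100):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, attempt]))
        seq = list(rng.choice(aas, size=L, p=probs))
        taken = np.zeros(L, dtype=bool)

        # flanking negatives pin the detected region to the planted span
        for p in (s0 - 1, e0 + 1):
            if 0 <= p < L:
                seq[p] = str(rng.choice(["D", "E"]))
                taken[p] = True

        # FG dipeptides, enriched inside the LCR
        n_fg = int(round(spec.fg_fraction * L))
        weights = np.ones(L - 1)
        weights[s0:e0] *= spec.lcr_fg_enrichment
        placed = 0
        order = rng.permutation(L - 1)
        order = order[np.argsort(-weights[order] * rng.random(L - 1))]
        for p in order:
            if placed >= n_fg:
                break
            if not taken[p] and not taken[p + 1]:
                seq[p], seq[p + 1] = "F", "G"
                taken[p] = taken[p + 1] = True
                placed += 1

        # positive charges inside the LCR
        inside = [i for i in range(s0, e0 + 1) if not taken[i]]
        if len(inside) < spec.lcr_n_positive:
            continue
        lcr_pos = rng.choice(inside, size=spec.lcr_n_positive, replace=False)
        for i in lcr_pos:
            seq[i] = "K"
            taken[i] = True

        # mixed background charges outside the LCR
        outside = [i for i in range(L) if not taken[i] and not s0 <= i <= e0]
        n_bg = int(round(spec.background_charge_density * (L - (e0 - s0 + 1))))
        n_bg = min(n_bg, len(outside))
        bg = np.sort(rng.choice(outside, size=n_bg, replace=False)) if n_bg else []
        n_pos = int(round(spec.background_positive_fraction * n_bg))
        signs = np.array([True] * n_pos + [False] * (n_bg - n_pos))
        rng.shuffle(signs)
        # break runs of consecutive positives: two adjacent background
        # positives could outgrow the planted region between rare negatives
        for k in range(1, n_bg):
            if signs[k] and signs[k - 1]:
                later = np.flatnonzero(~signs[k + 1:])
                if len(later):
                    j = k + 1 + later[0]
                    signs[k], signs[j] = signs[j], signs[k]
        for i, positive in zip(bg, signs):
            if positive:
                seq[i] = str(rng.choice(["K", "R"]))
            else:
                seq[i] = str(rng.choice(["D", "E"]))

        nup = NupSequence(name, "".join(seq))
        region = largest_positive_lcr(nup)
        if (
            region is not None
            and (region.start, region.end) == spec.lcr_span
            and region.n_charges == spec.lcr_n_positive
        ):
            from .sequences import assign_charges

            charges = assign_charges(nup)
            comp = {aa: nup.residues.count(aa) / L for aa in set(nup.residues)}
            report = {
                "planted_span": list(spec.lcr_span),
                "lcr_charge_positions": sorted(int(i) + 1 for i in lcr_pos),
                "fg_positions": find_fg_motifs(nup),
                "n_fg": len(find_fg_motifs(nup)),
                "net_charge": int(charges.sum()),
                "composition": comp,
                "attempts": attempt + 1,
            }
            return nup, report
    raise RuntimeError(
        "could not realize the planted LCR; spec constraints too tight"
    )


@dataclass
class FixturePair:
    wildtype: NupSequence
    mutant: NupSequence
    lcr_span: tuple
    lcr_charge_positions: list
    report: dict


@dataclass
class FixtureSuite:
    pairs: dict
    mini_ring: RingSpec
    micro_npc: NPCGeometry


def fixture_suite() -> FixtureSuite:
    """Small, fixed wildtype/mutant pairs plus reduced-size geometries.

    Sequences are 40-120 residues with hand-checkable planted LCRs; the
    mini ring and micro NPC are scaled-down geometries for integration tests.
    """
    specs = {
        "fix40": SyntheticNupSpec(length=40, fg_fraction=0.08,
                                  lcr_span=(10, 30), lcr_n_positive=3, seed=11),
        "fix60": SyntheticNupSpec(length=60, fg_fraction=0.08,
                                  lcr_span=(15, 40), lcr_n_positive=4, seed=12),
        "fix120": SyntheticNupSpec(length=120, fg_fraction=0.08,
                                   lcr_span=(31, 70), lcr_n_positive=6, seed=13),
    }
    pairs = {}
    for name, spec in specs.items():
        wt, report = generate_nup(spec, name=name)
        region = largest_positive_lcr(wt)
        mut = mutate_charged_to_ala(wt, region)
        pairs[name] = FixturePair(
            wildtype=wt,
            mutant=mut,
            lcr_span=(region.start, region.end),
            lcr_charge_positions=report["lcr_charge_positions"],
            report=report,
        )
    mini_ring = RingSpec(nup="fix60", ring_diameter=16.0, ring_height=10.0)
    sc = Scaffold(r_waist=8.0, r_end=12.0, half_length=6.0)
    micro_npc = NPCGeometry(
        scaffold=sc,
        sites=[
            AnchorSite("fix40", sc.radius_at(4.0) - 0.6, 4.0),
            AnchorSite("fix60", sc.radius_at(-4.0) - 0.6, -4.0),
        ],
    )
    return FixtureSuite(pairs=pairs, mini_ring=mini_ring, micro_npc=micro_npc)


def write_fixture_files(outdir) -> None:
    """Emit the fixture sequences as FASTA plus a JSON sidecar with the
    planted truth (LCR spans and charge positions)."""
    from pathlib import Path

    from .sequences import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suite = fixture_suite()
    seqs = []
    truth = {}
    for name, pair in suite.pairs.items():
        seqs.extend([pair.wildtype, pair.mutant])
        truth[name] = {
            "lcr_span": list(pair.lcr_span),
            "lcr_charge_positions": pair.lcr_charge_positions,
        }
    write_fasta(seqs, outdir / "fixtures.fasta")
    (outdir / "fixtures.json").write_text(json.dumps(truth, indent=2,
                                                     default=int))
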