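"""Sequence-level analysis of FG nucleoporins.

FG Nups are intrinsically disordered proteins whose sequences carry two
features this package cares about: FG dipeptide repeats (the cohesive,
hydrophobic motifs that form the permeability barrier of the nuclear pore
complex) and *like charge regions* (LCRs) — maximal stretches in which every
charged residue carries the same sign.  The largest positively charged LCR of
each Nup is the object of the charged-to-Ala mutagenesis experiments the rest
of the package simulates.

All reported positions are 1-based inclusive, matching the convention used
for protein sequence coordinates throughout the field.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Default side-chain charge convention at physiological pH.  Histidine is
#: treated as neutral; termini are uncharged because the domains handled here
#: are excised from longer proteins.
DEFAULT_CHARGES: dict[str, int] = {"K": 1, "R": 1, "D": -1, "E": -1}


@dataclass(frozen=True)
class NupSequence:
    """A named disordered-domain amino-acid sequence."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"{self.name}: empty sequence")
        for i, aa in enumerate(self.residues):
            if aa not in STANDARD_AA:
                raise ValueError(
                    f"{self.name}: unknown residue code {aa!r} at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class LikeChargeRegion:
    """A maximal interval whose charged residues all share one sign.

    ``start``/``end`` are 1-based inclusive.  ``n_charges`` counts the charged
    residues inside the interval; ``sign`` is +1 or -1.
    """

    start: int
    end: int
    sign: int
    n_charges: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def assign_charges(
    seq: NupSequence, convention: dict[str, int] | None = None
) -> np.ndarray:
    """Per-residue integer charges in {-1, 0, +1}.

    The default convention assigns K,R -> +1 and D,E -> -1 with histidine and
    all other residues neutral.
    """
    conv = DEFAULT_CHARGES if convention is None else convention
    return np.array([conv.get(aa, 0) for aa in seq.residues], dtype=np.int64)


def find_like_charge_regions(
    seq: NupSequence,
    min_charges: int = 2,
    convention: dict[str, int] | None = None,
) -> list[LikeChargeRegion]:
    """All maximal same-sign charge regions with at least ``min_charges`` charges.

    A region of sign *s* is the largest interval containing >= ``min_charges``
    charges of sign *s* and no charge of sign *-s*; it therefore extends to the
    residues adjacent to the nearest opposite-sign charges, or to the sequence
    ends.  Positive and negative regions may overlap (on the uncharged gap
    between a run of + and a run of -).  Regions are returned in ascending
    start order, positive before negative at equal start.
    """
    charges = assign_charges(seq, convention)
    n = len(charges)
    regions: list[LikeChargeRegion] = []
    for sign in (1, -1):
        # Maximal intervals free of opposite-sign charges are the segments
        # obtained by cutting the sequence at each opposite-sign charge.
        opp = np.flatnonzero(charges == -sign)
        bounds = np.concatenate([[-1], opp, [n]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            s, e = lo + 1, hi - 1  # 0-based inclusive segment
            if s > e:
                continue
            count = int(np.sum(charges[s : e + 1] == sign))
            if count >= min_charges:
                regions.append(LikeChargeRegion(s + 1, e + 1, sign, count))
    regions.sort(key=lambda r: (r.start, -r.sign))
    return regions


def largest_positive_lcr(
    seq: NupSequence,
    min_charges: int = 2,
    convention: dict[str, int] | None = None,
    size_metric: str = "span",
) -> LikeChargeRegion | None:
    """The largest positively charged LCR, or ``None`` if none exists.

    ``size_metric`` selects what "largest" means: ``"span"`` (residue length,
    the default) or ``"charges"`` (number of charged residues).  Ties break
    toward the smaller start position.
    """
    if size_metric not in ("span", "charges"):
        raise ValueError(f"unknown size metric {size_metric!r}")
    positives = [
        r
        for r in find_like_charge_regions(seq, min_charges, convention)
        if r.sign == 1
    ]
    if not positives:
        return None
    key = (lambda r: r.length) if size_metric == "span" else (lambda r: r.n_charges)
    best = max(positives, key=lambda r: (key(r), -r.start))
    return best


def find_fg_motifs(seq: NupSequence) -> list[int]:
    """1-based positions of the F residue of every FG dipeptide."""
    s = seq.residues
    return [i + 1 for i in range(len(s) - 1) if s[i] == "F" and s[i + 1] == "G"]


def mutate_charged_to_ala(
    seq: NupSequence,
    region: LikeChargeRegion,
    convention: dict[str, int] | None = None,
    suffix: str = "_mut",
) -> NupSequence:
    """Charged-to-Ala scan of a region: every charged residue inside
    [start, end] becomes alanine; everything else is untouched."""
    if region.start < 1 or region.end > len(seq):
        raise ValueError(
            f"region {region.start}-{region.end} outside 1-{len(seq)}"
        )
    charges = assign_charges(seq, convention)
    out = list(seq.residues)
    for i in range(region.start - 1, region.end):
        if charges[i] != 0:
            out[i] = "A"
    return NupSequence(seq.name + suffix, "".join(out))


def mutate_positions(
    seq: NupSequence, positions: Iterable[int], to: str = "A", suffix: str = "_mut"
) -> NupSequence:
    """Replace the residues at the given 1-based positions with ``to``."""
    if to not in STANDARD_AA:
        raise ValueError(f"target residue {to!r} is not a standard amino acid")
    out = list(seq.residues)
    for p in positions:
        if not 1 <= p <= len(seq):
            raise ValueError(f"position {p} outside 1-{len(seq)}")
        out[p - 1] = to
    return NupSequence(seq.name + suffix, "".join(out))


def read_fasta(path) -> list[NupSequence]:
    """Read a multi-record FASTA; record id becomes the Nup name."""
    return [
        NupSequence(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Sequence[NupSequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.name}\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i : i + 60] + "\n")


def region_report(
    seqs: Sequence[NupSequence], min_charges: int = 2
) -> "pd.DataFrame":
    """Tabular report of every detected LCR across a set of sequences."""
    import pandas as pd

    rows = []
    for s in seqs:
        for r in find_like_charge_regions(s, min_charges):
            rows.append(
                {
                    "name": s.name,
                    "start": r.start,
                    "end": r.end,
                    "sign": "+" if r.sign > 0 else "-",
                    "n_charges": r.n_charges,
                    "length": r.length,
                }
            )
    return pd.DataFrame(
        rows, columns=["name", "start", "end", "sign", "n_charges", "length"]
    )
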