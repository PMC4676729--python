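"""Build the three simulated arrangements: isolated Nup, eightfold ring,
whole NPC.

Chains start from self-avoiding random walks with the model bond length
(0.38 nm); anchored chains grow inward from their tether point.  Anchors are
realized by freezing the tether bead in place (infinite-mass convention).
The NPC scaffold is a rigid hourglass surface of revolution, optionally
decorated with spherical blobs, that interacts with beads through excluded
volume only.

The ring diameters and the hourglass profile of the yeast NPC are supplied
through a geometry configuration; the defaults shipped here are documented
placeholders with the right overall dimensions (a ~35 nm long channel
widening from a ~40 nm waist toward ~70 nm at the ends), not measured
anchor coordinates.  Publication-grade runs must set them explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .forcefield import ForceFieldParams, beads_from_sequence
from .sequences import (
    NupSequence,
    find_fg_motifs,
    largest_positive_lcr,
    mutate_charged_to_ala,
)
from .system import Scaffold, System


@dataclass(frozen=True)
class RingSpec:
    """Eight copies of one Nup tethered on a circle."""

    nup: str
    ring_diameter: float                  # nm, = NPC diameter at the tether z
    n_copies: int = 8
    ring_height: float = 10.0             # nm, analysis-cylinder length
    anchor_z: float = 0.0

    def __post_init__(self):
        if not self.ring_diameter or self.ring_diameter <= 0:
            raise ValueError(f"ring diameter missing for {self.nup}")


@dataclass
class AnchorSite:
    """One Nup's tether location, replicated eightfold about the pore axis."""

    nup: str
    radius: float
    z: float
    terminus: str = "C"                   # which terminus is anchored


@dataclass
class NPCGeometry:
    """Scaffold profile plus per-Nup anchor sites (eightfold symmetric)."""

    scaffold: Scaffold = field(default_factory=Scaffold)
    sites: list[AnchorSite] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "NPCGeometry":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        sc = doc.get("scaffold", {})
        blobs = np.asarray(sc.get("blobs", []), float).reshape(-1, 4)
        scaffold = Scaffold(
            r_waist=float(sc.get("r_waist", 20.0)),
            r_end=float(sc.get("r_end", 35.0)),
            half_length=float(sc.get("half_length", 17.5)),
            contact=float(sc.get("contact", 0.3)),
            k_wall=float(sc.get("k_wall", 500.0)),
            blobs=blobs,
        )
        sites = [
            AnchorSite(s["nup"], float(s["radius"]), float(s["z"]),
                       s.get("terminus", "C"))
            for s in doc.get("anchors", [])
        ]
        return cls(scaffold, sites)


#: Nups whose largest LCR is positively charged; these are the ones mutated
#: in the charge-neutralized NPC variant.
POSITIVE_LCR_NUPS = (
    "Nsp1", "Nup42", "Nup49", "Nup57", "Nup100", "Nup116", "Nup145N",
)
#: Nups without a positive LCR: wildtype sequences are used in both variants.
NO_POSITIVE_LCR_NUPS = ("Nup1", "Nup2", "Nup159", "Nup60")


def _clash(cand, occupied, d_min):
    if len(occupied) == 0:
        return False
    d2 = np.sum((occupied - cand) ** 2, axis=1)
    return bool(np.any(d2 < d_min * d_min))


def _scaffold_ok(p, scaffold: Scaffold | None) -> bool:
    if scaffold is None:
        return True
    if abs(p[2]) <= scaffold.half_length:
        rho = np.hypot(p[0], p[1])
        if rho > scaffold.radius_at(p[2]) - scaffold.contact:
            return False
    for b in scaffold.blobs:
        if np.sum((p - b[:3]) ** 2) < (b[3] + scaffold.contact) ** 2:
            return False
    return True


def self_avoiding_walk(
    n: int,
    rng: np.random.Generator,
    start=(0.0, 0.0, 0.0),
    direction=None,
    bond: float = 0.38,
    d_min: float = 0.6,
    occupied: np.ndarray | None = None,
    scaffold: Scaffold | None = None,
    max_bend_deg: float = 75.0,
):
    """Grow an n-bead self-avoiding walk with fixed bond length.

    No two beads separated by >= 2 bonds (nor any bead of ``occupied``) come
    closer than ``d_min``; consecutive bond directions deviate by at most
    ``max_bend_deg``.  Backtracks when stuck; raises if the walk cannot be
    completed within a generous retry budget.
    """
    pts = np.empty((n, 3))
    pts[0] = start
    if n == 1:
        return pts
    if direction is None:
        v = rng.standard_normal(3)
        direction = v / np.linalg.norm(v)
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    occ = np.zeros((0, 3)) if occupied is None else occupied

    def candidate(prev_dir):
        beta = np.deg2rad(max_bend_deg) * rng.random()
        az = 2.0 * np.pi * rng.random()
        # orthonormal frame around prev_dir
        a = np.array([1.0, 0.0, 0.0])
        if abs(prev_dir[0]) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(prev_dir, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(prev_dir, e1)
        return (
            np.cos(beta) * prev_dir
            + np.sin(beta) * (np.cos(az) * e1 + np.sin(az) * e2)
        )

    budget = 200 * n
    i = 1
    dirs = [direction]
    while i < n:
        placed = False
        for trial in range(60):
            budget -= 1
            if i == 1:
                # retry the seed direction with growing jitter if blocked
                d = direction + (0.4 * trial / 60.0) * rng.standard_normal(3)
                d = d / np.linalg.norm(d)
            else:
                d = candidate(dirs[-1])
            cand = pts[i - 1] + bond * d
            prior = pts[: max(i - 1, 0)]  # beads >= 2 bonds back
            if (
                not _clash(cand, prior, d_min)
                and not _clash(cand, occ, d_min)
                and _scaffold_ok(cand, scaffold)
            ):
                pts[i] = cand
                dirs.append(d)
                placed = True
                break
        if placed:
            i += 1
        else:
            back = min(10, i - 1)
            i -= back
            del dirs[len(dirs) - back:]
        if budget <= 0:
            raise RuntimeError(f"self-avoiding walk stuck at bead {i}/{n}")
    return pts


def build_single(
    seq: NupSequence,
    params: ForceFieldParams | None = None,
    seed: int = 0,
    confine_radius: float = 0.0,
) -> System:
    """One free chain (no tether, no scaffold) from a self-avoiding walk."""
    params = params or ForceFieldParams()
    rng = np.random.default_rng(seed)
    n = len(seq)
    pos = self_avoiding_walk(n, rng, bond=params.bond_length,
                             d_min=params.lj_sigma)
    pos -= pos.mean(axis=0)
    masses, charges, h = beads_from_sequence(seq, params)
    markers = np.array([p - 1 for p in find_fg_motifs(seq)], dtype=np.int64)
    return System(
        positions=pos,
        masses=masses,
        charges=charges,
        hydrophobicity=h,
        chain_id=np.zeros(n, dtype=np.int64),
        fixed=np.zeros(n, dtype=bool),
        fg_markers=markers,
        confine_radius=confine_radius,
        names=(seq.name,),
    )


def _tethered_chain(seq, params, anchor, inward, rng, occupied, scaffold,
                    terminus):
    """Positions for one anchored chain grown inward from the tether point."""
    n = len(seq)
    jitter = 0.2 * rng.standard_normal(3)
    d0 = inward + jitter
    d0 /= np.linalg.norm(d0)
    pts = self_avoiding_walk(
        n, rng, start=anchor, direction=d0, bond=params.bond_length,
        d_min=params.lj_sigma, occupied=occupied, scaffold=scaffold,
    )
    if terminus == "C":
        pts = pts[::-1].copy()  # bead order stays N->C; anchor = last bead
    return pts


def _assemble(seqs, chains_pos, anchored_bead, params, scaffold=None,
              names=(), convention=None) -> System:
    pos, masses, charges, h, cid, fixed, markers = [], [], [], [], [], [], []
    offset = 0
    for c, (seq, pts) in enumerate(zip(seqs, chains_pos)):
        m, q, hh = beads_from_sequence(seq, params, convention)
        pos.append(pts)
        masses.append(m)
        charges.append(q)
        h.append(hh)
        cid.append(np.full(len(seq), c, dtype=np.int64))
        fx = np.zeros(len(seq), dtype=bool)
        if anchored_bead[c] is not None:
            fx[anchored_bead[c]] = True
        fixed.append(fx)
        markers.extend(offset + p - 1 for p in find_fg_motifs(seq))
        offset += len(seq)
    return System(
        positions=np.concatenate(pos),
        masses=np.concatenate(masses),
        charges=np.concatenate(charges),
        hydrophobicity=np.concatenate(h),
        chain_id=np.concatenate(cid),
        fixed=np.concatenate(fixed),
        fg_markers=np.array(markers, dtype=np.int64),
        scaffold=scaffold,
        names=tuple(names),
    )


def build_ring(
    spec: RingSpec,
    seq: NupSequence,
    params: ForceFieldParams | None = None,
    seed: int = 0,
    terminus: str = "C",
    scaffold: Scaffold | None = None,
) -> System:
    """Eight copies of one Nup tethered at 45-degree spacing on a circle of
    radius ``ring_diameter / 2``, initial conformations pointing inward."""
    params = params or ForceFieldParams()
    rng = np.random.default_rng(seed)
    radius = spec.ring_diameter / 2.0
    seqs, chains, anchored = [], [], []
    occupied = np.zeros((0, 3))
    for k in range(spec.n_copies):
        ang = 2.0 * np.pi * k / spec.n_copies
        anchor = np.array(
            [radius * np.cos(ang), radius * np.sin(ang), spec.anchor_z]
        )
        inward = np.array([-np.cos(ang), -np.sin(ang), 0.0])
        pts = _tethered_chain(seq, params, anchor, inward, rng, occupied,
                              scaffold, terminus)
        seqs.append(seq)
        chains.append(pts)
        anchored.append(len(seq) - 1 if terminus == "C" else 0)
        occupied = np.concatenate([occupied, pts])
    sys_ = _assemble(seqs, chains, anchored, params, scaffold=scaffold,
                     names=[f"{seq.name}#{k}" for k in range(spec.n_copies)])
    sys_.meta["ring_spec"] = spec
    return sys_


def build_npc(
    geometry: NPCGeometry,
    sequences: dict[str, NupSequence],
    params: ForceFieldParams | None = None,
    seed: int = 0,
    mutant: bool = False,
    positive_lcr_nups: tuple[str, ...] = POSITIVE_LCR_NUPS,
) -> System:
    """Whole-NPC system: every anchor site replicated eightfold, chains
    tethered on the hourglass scaffold.

    With ``mutant=True``, the charged-to-Ala LCR mutation is applied to the
    Nups listed in ``positive_lcr_nups`` (those whose largest LCR is
    positive); all other Nups keep their wildtype sequence.
    """
    params = params or ForceFieldParams()
    rng = np.random.default_rng(seed)
    sc = geometry.scaffold
    seqs, chains, anchored, names = [], [], [], []
    occupied = np.zeros((0, 3))
    for site in geometry.sites:
        seq = sequences[site.nup]
        if mutant and site.nup in positive_lcr_nups:
            region = largest_positive_lcr(seq)
            if region is None:
                raise ValueError(f"{site.nup} listed as positive-LCR but none found")
            seq = mutate_charged_to_ala(seq, region)
        if abs(site.z) <= sc.half_length and site.radius > sc.radius_at(site.z):
            raise ValueError(f"anchor for {site.nup} lies inside the scaffold solid")
        for k in range(8):
            ang = 2.0 * np.pi * k / 8.0
            anchor = np.array(
                [site.radius * np.cos(ang), site.radius * np.sin(ang), site.z]
            )
            inward = np.array([-np.cos(ang), -np.sin(ang), 0.0])
            pts = _tethered_chain(seq, params, anchor, inward, rng, occupied,
                                  sc, site.terminus)
            seqs.append(seq)
            chains.append(pts)
            anchored.append(len(seq) - 1 if site.terminus == "C" else 0)
            names.append(f"{seq.name}#{k}")
            occupied = np.concatenate([occupied, pts])
    sys_ = _assemble(seqs, chains, anchored, params, scaffold=sc, names=names)
    sys_.meta["variant"] = "mutant" if mutant else "wildtype"
    return sys_


def scaffold_force(position, scaffold: Scaffold, k_wall: float | None = None):
    """Excluded-volume force the scaffold exerts on a single point.

    Purely repulsive, directed along the inward surface normal, zero beyond
    the contact range.
    """
    from . import _kernels

    pos = np.asarray(position, float).reshape(1, 3)
    forces = np.zeros_like(pos)
    sc = scaffold if k_wall is None else Scaffold(
        scaffold.r_waist, scaffold.r_end, scaffold.half_length,
        scaffold.contact, k_wall, scaffold.blobs,
    )
    empty_i = np.zeros(0, np.int64)
    _kernels.compute_forces(
        pos, forces,
        np.zeros((0, 2), np.int64), 0.0, 0.38,
        np.zeros((0, 3), np.int64), 0, 0.0, 2.0, 0.0, 1.0,
        np.zeros(2), np.zeros(2),
        np.zeros((0, 4), np.int64), 0, np.zeros(1), np.ones(1), np.zeros(1),
        0.0, 1.0, np.zeros(2), np.zeros(2),
        empty_i, empty_i, 0, empty_i, empty_i, 0,
        0.6, 1.0, 0.0, False, np.zeros(1), np.zeros(1), np.zeros(1),
        0.0, 1.0, 2.5, 5.0,
        True, sc.r_waist, sc.r_end, sc.half_length, sc.contact, sc.k_wall,
        np.ascontiguousarray(sc.blobs, float),
        0.0, 0.0,
        False, False, False,
    )
    return forces[0]


def default_npc_geometry() -> NPCGeometry:
    """Placeholder yeast-NPC geometry with the documented hourglass profile.

    Anchor radii sit on the wall at each site's axial position; the axial
    positions themselves are plausible placeholders (cytoplasmic Nups high,
    nucleoplasmic Nups low), not measured coordinates.
    """
    sc = Scaffold()
    zs = {
        "Nup159": 16.0, "Nup42": 14.0, "Nup116": 12.0, "Nsp1": 10.0,
        "Nup100": 6.0, "Nup57": 4.0, "Nup49": 2.0, "Nup145N": -6.0,
        "Nup2": -10.0, "Nup60": -12.0, "Nup1": -14.0,
    }
    sites = [
        AnchorSite(nup, sc.radius_at(z) - 2.0 * sc.contact, z)
        for nup, z in zs.items()
    ]
    return NPCGeometry(sc, sites)
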