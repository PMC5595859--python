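"""Evaluation of the ten brivudine-derived interaction patterns A-J.

The patterns describe how the antiviral drug brivudine (BVDU) binds its
kinase targets: a stacked aromatic base ring (A), double pi-stacking
variants (B-D), paired hydrogen bonds on the ring moiety (E-G), and
distal contacts whose ligand anchors sit in characteristic distance
bands from the base ring (H: hydrophobic, I: hydrogen bond, J: halogen
bond).  Every pattern presupposes A; a complex without a stacked ligand
ring scores zero.

All patterns are evaluated relative to one candidate "base ring": a
ligand aromatic ring engaged in at least one pi-stacking interaction.
The complex-level result is the best single base ring (no union across
rings).  Distal distances ``x`` are measured from the ligand-side
interaction anchor to the base-ring centroid and compared against the
published bands with strict inequalities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .config import PatternConfig
from .interactions import (HydrogenBond, InteractionProfile, PiStacking,
                           vector_angle)
from .structure_io import AromaticRing

__all__ = [
    "PATTERN_IDS",
    "PATTERN_IMPLICATIONS",
    "BaseRingContext",
    "PatternEvaluation",
    "candidate_base_rings",
    "evaluate_patterns",
    "best_evaluation",
    "closed_pattern_subsets",
    "is_implication_closed",
]

PATTERN_IDS = tuple("ABCDEFGHIJ")

#: pattern -> its immediate prerequisite
PATTERN_IMPLICATIONS: dict[str, str] = {
    "B": "A", "C": "B", "D": "B",
    "E": "A", "F": "E", "G": "E",
    "H": "A", "I": "A", "J": "A",
}


def is_implication_closed(subset) -> bool:
    """True when a pattern subset respects all prerequisite implications."""
    s = set(subset)
    if s and "A" not in s:
        return False
    return all(PATTERN_IMPLICATIONS[p] in s for p in s if p != "A")


def closed_pattern_subsets(include_empty: bool = True) -> list[frozenset[str]]:
    """All implication-closed subsets of {A..J}, sorted canonically."""
    from itertools import product
    b_opts = [frozenset(), frozenset("B"), frozenset("BC"),
              frozenset("BD"), frozenset("BCD")]
    e_opts = [frozenset(), frozenset("E"), frozenset("EF"),
              frozenset("EG"), frozenset("EFG")]
    distal_opts = []
    for h, i, j in product([False, True], repeat=3):
        distal_opts.append(frozenset(
            ([("H")] if h else []) + ([("I")] if i else [])
            + ([("J")] if j else [])))
    subsets = set()
    if include_empty:
        subsets.add(frozenset())
    for b, e, d in product(b_opts, e_opts, distal_opts):
        subsets.add(frozenset("A") | b | e | d)
    return sorted(subsets, key=lambda s: (len(s), "".join(sorted(s))))


@dataclass
class BaseRingContext:
    """Everything pattern evaluation needs about one candidate base ring."""

    ring: AromaticRing
    stacks: list[PiStacking]
    #: hydrogen bonds anchored on the ring moiety (members + exocyclic
    #: atoms covalently bonded to a member)
    moiety_hbonds: list[HydrogenBond]
    #: (contact, x) with x = hydrophobic ligand atom to ring centroid
    distal_hydrophobic: list[tuple] = field(default_factory=list)
    #: (hbond, x) with x = ligand anchor atom to ring centroid
    distal_hbonds: list[tuple] = field(default_factory=list)
    #: (halogen bond, x) with x = halogen atom to ring centroid
    distal_halogen: list[tuple] = field(default_factory=list)
    #: donor->acceptor direction vectors of the moiety hydrogen bonds
    hbond_vectors: dict[tuple[int, int], tuple[float, float, float]] = field(
        default_factory=dict)


@dataclass
class PatternEvaluation:
    """Per-base-ring pattern flags with supporting evidence."""

    base_ring: AromaticRing | None
    flags: dict[str, bool]
    evidence: dict[str, list] = field(default_factory=dict)

    @property
    def count(self) -> int:
        return sum(bool(v) for v in self.flags.values())

    @property
    def pattern_set(self) -> frozenset[str]:
        return frozenset(p for p, v in self.flags.items() if v)

    def to_dict(self) -> dict:
        return {
            "base_ring": list(self.base_ring.member_serials)
            if self.base_ring else None,
            "flags": {p: bool(self.flags[p]) for p in PATTERN_IDS},
            "count": self.count,
            "evidence": {p: self.evidence.get(p, []) for p in PATTERN_IDS
                         if self.flags.get(p)},
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    @staticmethod
    def empty() -> "PatternEvaluation":
        return PatternEvaluation(
            base_ring=None, flags={p: False for p in PATTERN_IDS})


def candidate_base_rings(profile: InteractionProfile) -> list[BaseRingContext]:
    """Build one evaluation context per stacked ligand ring.

    A ligand aromatic ring qualifies as a candidate base ring when it
    participates in at least one pi-stacking interaction (pattern A is
    a prerequisite for all others).  Contexts carry the ring's stacks,
    the hydrogen bonds anchored on its moiety, and distal interaction
    candidates annotated with their anchor-to-centroid distances.
    """
    site = profile.complex
    if site is None:
        raise ValueError("profile carries no binding-site complex")
    nm = site.neighbor_map()
    contexts = []
    for ring in sorted(site.ligand_rings, key=lambda r: r.member_serials):
        stacks = [s for s in profile.pi_stacks
                  if s.ligand_ring.member_serials == ring.member_serials]
        if not stacks:
            continue
        members = set(ring.member_serials)
        moiety = set(members)
        for m in members:
            moiety.update(nm.get(m, []))

        cen = ring.centroid_xyz
        moiety_hbonds = []
        vectors: dict[tuple[int, int], tuple[float, float, float]] = {}
        distal_hb = []
        for hb in profile.hydrogen_bonds:
            if hb.ligand_anchor_serial in moiety:
                moiety_hbonds.append(hb)
                don = site.atom(hb.donor_serial).xyz
                acc = site.atom(hb.acceptor_serial).xyz
                v = acc - don
                n = np.linalg.norm(v)
                if n > 1e-12:
                    v = v / n
                vectors[(hb.donor_serial, hb.acceptor_serial)] = tuple(v)
            x = float(np.linalg.norm(
                site.atom(hb.ligand_anchor_serial).xyz - cen))
            distal_hb.append((hb, x))

        distal_hc = []
        for hc in profile.hydrophobic_contacts:
            x = float(np.linalg.norm(site.atom(hc.ligand_serial).xyz - cen))
            distal_hc.append((hc, x))

        distal_xb = []
        for xb in profile.halogen_bonds:
            x = float(np.linalg.norm(site.atom(xb.halogen_serial).xyz - cen))
            distal_xb.append((xb, x))

        contexts.append(BaseRingContext(
            ring=ring, stacks=stacks, moiety_hbonds=moiety_hbonds,
            distal_hydrophobic=distal_hc, distal_hbonds=distal_hb,
            distal_halogen=distal_xb, hbond_vectors=vectors))
    return contexts


def evaluate_patterns(context: BaseRingContext,
                      config: PatternConfig | None = None,
                      ) -> PatternEvaluation:
    """Evaluate patterns A-J on one base-ring context.

    A is true by construction (the context exists only for stacked
    rings).  B requires a second stack from a distinct protein ring;
    C additionally stacks on opposite faces, D additionally two
    face-to-face (parallel type) stacks.  E requires two distinct
    moiety hydrogen bonds; F two such bonds to one protein residue;
    G a pair of bonds whose directed donor->acceptor vectors are
    antiparallel within the configured tolerance.  H, I and J test the
    distal distance bands with strict inequalities.
    """
    cfg = config or PatternConfig()
    flags = {p: False for p in PATTERN_IDS}
    evidence: dict[str, list] = {}

    def stack_ev(s: PiStacking) -> dict:
        return {"protein_ring": list(s.protein_ring.member_serials),
                "distance": round(s.centroid_distance, 3),
                "type": s.stack_type, "face_sign": s.face_sign}

    def hb_ev(h: HydrogenBond, x: float | None = None) -> dict:
        d = {"donor": h.donor_serial, "acceptor": h.acceptor_serial,
             "distance": round(h.da_distance, 3)}
        if x is not None:
            d["x"] = round(x, 3)
        return d

    flags["A"] = True
    evidence["A"] = [stack_ev(s) for s in context.stacks]

    distinct_prot_rings = {s.protein_ring.key for s in context.stacks}
    if len(context.stacks) >= 2 and len(distinct_prot_rings) >= 2:
        flags["B"] = True
        evidence["B"] = [stack_ev(s) for s in context.stacks]
    if flags["B"]:
        signs = {s.face_sign for s in context.stacks}
        if {1, -1} <= signs:
            flags["C"] = True
            evidence["C"] = [stack_ev(s) for s in context.stacks]
        parallel = [s for s in context.stacks if s.stack_type == "parallel"]
        if (len(parallel) >= 2
                and len({s.protein_ring.key for s in parallel}) >= 2):
            flags["D"] = True
            evidence["D"] = [stack_ev(s) for s in parallel]

    hbonds = context.moiety_hbonds
    if len(hbonds) >= 2:
        flags["E"] = True
        evidence["E"] = [hb_ev(h) for h in hbonds]
        # F: some pair of moiety bonds shares one protein residue
        # (residue tags attached by best_evaluation; same-atom pairs
        # count as shared when tags are unavailable)
        shared = _shared_residue_pairs(context)
        if shared:
            flags["F"] = True
            evidence["F"] = [[hb_ev(a), hb_ev(b)] for a, b in shared]
        # G: antiparallel directed donor->acceptor vectors
        lo = cfg.parallel_hbond_angle_center - cfg.parallel_hbond_tolerance
        hi = cfg.parallel_hbond_angle_center + cfg.parallel_hbond_tolerance
        g_pairs = []
        for i in range(len(hbonds)):
            for j in range(i + 1, len(hbonds)):
                vi = context.hbond_vectors.get(
                    (hbonds[i].donor_serial, hbonds[i].acceptor_serial))
                vj = context.hbond_vectors.get(
                    (hbonds[j].donor_serial, hbonds[j].acceptor_serial))
                if vi is None or vj is None:
                    continue
                ang = vector_angle(np.asarray(vi), np.asarray(vj))
                if lo <= ang <= hi:
                    g_pairs.append((hbonds[i], hbonds[j], ang))
        if g_pairs:
            flags["G"] = True
            evidence["G"] = [
                {"pair": [hb_ev(a), hb_ev(b)], "angle": round(ang, 2)}
                for a, b, ang in g_pairs]

    lo, hi = cfg.distal_hydrophobic_band
    h_hits = [(c, x) for c, x in context.distal_hydrophobic if lo < x < hi]
    if h_hits:
        flags["H"] = True
        evidence["H"] = [{"ligand": c.ligand_serial, "protein": c.protein_serial,
                          "x": round(x, 3)} for c, x in h_hits]

    lo, hi = cfg.distal_hbond_band
    i_hits = [(h, x) for h, x in context.distal_hbonds if lo < x < hi]
    if i_hits:
        flags["I"] = True
        evidence["I"] = [hb_ev(h, x) for h, x in i_hits]

    lo, hi = cfg.distal_halogen_band
    j_hits = [(b, x) for b, x in context.distal_halogen if lo < x < hi]
    if j_hits:
        flags["J"] = True
        evidence["J"] = [{"halogen": b.halogen_serial,
                          "acceptor": b.acceptor_serial,
                          "x": round(x, 3)} for b, x in j_hits]

    return PatternEvaluation(base_ring=context.ring, flags=flags,
                             evidence=evidence)


def _shared_residue_pairs(context: BaseRingContext):
    """Pairs of distinct moiety hydrogen bonds to the same protein residue."""
    residues = getattr(context, "_protein_residues", None)
    pairs = []
    hbonds = context.moiety_hbonds
    for i in range(len(hbonds)):
        for j in range(i + 1, len(hbonds)):
            a, b = hbonds[i], hbonds[j]
            pa = a.acceptor_serial if a.ligand_is_donor else a.donor_serial
            pb = b.acceptor_serial if b.ligand_is_donor else b.donor_serial
            if residues is not None:
                if residues.get(pa) == residues.get(pb) \
                        and residues.get(pa) is not None:
                    pairs.append((a, b))
            elif pa == pb:
                pairs.append((a, b))
    return pairs


def _attach_residues(profile: InteractionProfile,
                     contexts: list[BaseRingContext]) -> None:
    site = profile.complex
    if site is None:
        return
    res = {}
    for a in site.protein_atoms + site.context_atoms:
        res[a.serial] = a.residue_key
    for ctx in contexts:
        ctx._protein_residues = res


def best_evaluation(profile: InteractionProfile,
                    config: PatternConfig | None = None,
                    ) -> PatternEvaluation:
    """Evaluate every candidate base ring and return the best one.

    Ties on the pattern count are broken toward the ring that comes
    first in canonical atom order.  A profile with no stacked ligand
    ring yields the empty evaluation (all flags false, count 0).
    """
    contexts = candidate_base_rings(profile)
    _attach_residues(profile, contexts)
    if not contexts:
        return PatternEvaluation.empty()
    evals = [evaluate_patterns(c, config) for c in contexts]
    best = max(enumerate(evals), key=lambda iv: (iv[1].count, -iv[0]))
    return best[1]
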