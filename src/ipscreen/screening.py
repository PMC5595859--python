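"""Collection-level screening: score, aggregate, rank, annotate.

Runs the pattern evaluation over a collection of structures, keeps the
best complex per ligand component ("best-complex aggregation"), ranks
ligands by their pattern count and annotates drug status from an
optional user-supplied table.
"""

from __future__ import annotations

import json
import logging
import os
from collections import Counter
from dataclasses import dataclass, field

from .config import RunConfig
from .interactions import profile_complex
from .patterns import PATTERN_IDS, best_evaluation
from .structure_io import build_binding_site, parse_structure, select_ligands

__all__ = [
    "ComplexScore",
    "LigandRanking",
    "ScreenReport",
    "DrugTableError",
    "screen_collection",
    "aggregate_by_ligand",
    "rank_and_annotate",
    "load_drug_table",
]

logger = logging.getLogger(__name__)

DRUG_STATUSES = ("none", "experimental", "clinical", "approved")


class DrugTableError(ValueError):
    """Malformed drug-status table."""


@dataclass(frozen=True)
class ComplexScore:
    """Pattern evaluation result for one structure/ligand-instance pair."""

    structure_id: str
    component_id: str
    chain: str
    residue_number: int
    flags: dict[str, bool]
    count: int

    def __post_init__(self):
        if self.count != sum(bool(v) for v in self.flags.values()):
            raise ValueError("count inconsistent with flags")


@dataclass
class LigandRanking:
    """Best complex per ligand component, with drug annotation."""

    component_id: str
    best_count: int
    best_structure: str
    flags: dict[str, bool]
    n_complexes: int
    drug_status: str = "none"


@dataclass
class ScreenReport:
    """Ranked screen output plus run metadata."""

    rankings: list[LigandRanking]
    histogram: dict[int, int]
    hits: list[LigandRanking]
    min_count: int
    config: RunConfig = field(default_factory=RunConfig)
    n_structures: int = 0
    n_complexes: int = 0
    n_failures: int = 0

    def to_dict(self) -> dict:
        return {
            "rankings": [{
                "rank": i + 1,
                "component_id": r.component_id,
                "best_count": r.best_count,
                "flags": {p: bool(r.flags[p]) for p in PATTERN_IDS},
                "best_structure": r.best_structure,
                "n_complexes": r.n_complexes,
                "drug_status": r.drug_status,
            } for i, r in enumerate(self.rankings)],
            "histogram": {str(k): self.histogram[k] for k in sorted(self.histogram)},
            "n_hits": len(self.hits),
            "min_count": self.min_count,
            "census": {"structures": self.n_structures,
                       "complexes": self.n_complexes,
                       "failures": self.n_failures},
            "config": self.config.to_dict(),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def to_tsv(self) -> str:
        header = (["rank", "component_id", "best_count"]
                  + list(PATTERN_IDS)
                  + ["best_structure", "n_complexes", "drug_status"])
        rows = ["\t".join(header)]
        for i, r in enumerate(self.rankings):
            rows.append("\t".join(
                [str(i + 1), r.component_id, str(r.best_count)]
                + ["1" if r.flags[p] else "0" for p in PATTERN_IDS]
                + [r.best_structure, str(r.n_complexes), r.drug_status]))
        return "\n".join(rows) + "\n"


def _score_model(model, allowlist, cfg: RunConfig) -> list[ComplexScore]:
    scores = []
    for lig in select_ligands(model, allowlist=allowlist):
        site = build_binding_site(model, lig,
                                  cutoff=cfg.detection.binding_site_cutoff,
                                  config=cfg.detection)
        profile = profile_complex(site, cfg.detection)
        ev = best_evaluation(profile, cfg.patterns)
        scores.append(ComplexScore(
            structure_id=model.identifier,
            component_id=lig.component_id,
            chain=lig.chain,
            residue_number=lig.residue_number,
            flags=dict(ev.flags),
            count=ev.count))
    return scores


def screen_collection(sources, allowlist=None,
                      config: RunConfig | None = None,
                      ) -> list[ComplexScore]:
    """Score every ligand instance in a structure collection.

    ``sources`` is an iterable of structure file paths, of
    ``(identifier, pdb_text)`` pairs, or of already parsed
    :class:`~ipscreen.structure_io.StructureModel` objects.  Per-structure
    failures are logged and skipped; the screen only fails outright when
    no structure can be read at all.
    """
    from .structure_io import StructureModel

    cfg = config or RunConfig()
    scores: list[ComplexScore] = []
    n_read = 0
    n_fail = 0
    for src in sources:
        try:
            if isinstance(src, StructureModel):
                model = src
            elif isinstance(src, tuple):
                ident, text = src
                model = parse_structure(text, "pdb", identifier=ident)
            else:
                fmt = "mmcif" if str(src).endswith((".cif", ".mmcif")) else "pdb"
                model = parse_structure(src, fmt)
            n_read += 1
            scores.extend(_score_model(model, allowlist, cfg))
        except Exception as exc:  # noqa: BLE001 - robustness over a collection
            n_fail += 1
            name = getattr(src, "identifier", None) or (
                src[0] if isinstance(src, tuple) else os.fspath(src)
                if isinstance(src, (str, os.PathLike)) else repr(src))
            logger.warning("skipping %s: %s", name, exc)
    if n_read == 0:
        raise ValueError("no readable structure in the collection")
    return scores


def aggregate_by_ligand(scores: list[ComplexScore]) -> list[LigandRanking]:
    """Best-complex aggregation: keep the max-count complex per component.

    Ties between complexes of the same ligand are broken toward the
    lexicographically smallest structure id.
    """
    if not scores:
        raise ValueError("no complex scores to aggregate")
    groups: dict[str, list[ComplexScore]] = {}
    for sc in scores:
        groups.setdefault(sc.component_id, []).append(sc)
    out = []
    for comp, group in sorted(groups.items()):
        best = min(group, key=lambda sc: (-sc.count, sc.structure_id,
                                          sc.chain, sc.residue_number))
        out.append(LigandRanking(
            component_id=comp, best_count=best.count,
            best_structure=best.structure_id, flags=dict(best.flags),
            n_complexes=len(group)))
    return out


def load_drug_table(path) -> dict[str, str]:
    """Read a TSV mapping ``component_id`` to drug status."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = [c.lower() for c in df.columns]
    for col in ("component_id", "drug_status"):
        if col not in cols:
            raise DrugTableError(f"drug table missing column {col!r}")
    df.columns = cols
    return {str(r.component_id).strip(): str(r.drug_status).strip().lower()
            for r in df.itertuples(index=False)}


def rank_and_annotate(rankings: list[LigandRanking],
                      drug_table: dict[str, str] | None = None,
                      min_count: int = 6,
                      config: RunConfig | None = None,
                      n_structures: int = 0,
                      n_complexes: int = 0,
                      n_failures: int = 0) -> ScreenReport:
    """Sort ligands by pattern count, flag hits, join drug status.

    Sorting is by count descending with ties broken by component id
    ascending.  Entries with ``count >= min_count`` are reported as
    hits.  The histogram covers counts 0-10 and sums to the number of
    ligands.
    """
    if drug_table:
        bad = {v for v in drug_table.values() if v not in DRUG_STATUSES}
        if bad:
            raise DrugTableError(
                f"unknown drug_status values: {sorted(bad)}; "
                f"expected one of {DRUG_STATUSES}")
    annotated = []
    for r in rankings:
        status = (drug_table or {}).get(r.component_id, "none")
        annotated.append(LigandRanking(
            component_id=r.component_id, best_count=r.best_count,
            best_structure=r.best_structure, flags=dict(r.flags),
            n_complexes=r.n_complexes, drug_status=status))
    annotated.sort(key=lambda r: (-r.best_count, r.component_id))
    hist = Counter(r.best_count for r in annotated)
    histogram = {k: hist.get(k, 0) for k in range(11)}
    hits = [r for r in annotated if r.best_count >= min_count]
    return ScreenReport(
        rankings=annotated, histogram=histogram, hits=hits,
        min_count=min_count, config=config or RunConfig(),
        n_structures=n_structures, n_complexes=n_complexes,
        n_failures=n_failures)
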