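"""Hit prioritization: scaffold-aware similarity clustering and the
repositioning evidence matrix.

Two independent capabilities support triage of screen hits:

* chemical-similarity analysis — pairwise 2D-fingerprint Tanimoto
  similarity, with compounds grouped by scaffold and ordered within
  each scaffold by average-linkage hierarchical clustering.  This
  surfaces hits whose chemical core differs from the query drug
  (scaffold hopping).
* repositioning evidence matrix — a drug-class by target-superfamily
  grid annotating whether binding evidence exists from crystal
  structures ("structural") or from other sources such as assays or
  text mining ("other"), with coverage percentages over all cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CompoundEntry",
    "SimilarityMatrix",
    "EvidenceMatrix",
    "CoverageStats",
    "similarity_matrix",
    "cluster_within_scaffolds",
    "murcko_scaffold",
    "build_evidence_matrix",
    "coverage_stats",
]

EVIDENCE_KINDS = ("structural", "other")


@dataclass(frozen=True)
class CompoundEntry:
    """One screened compound: identifier, SMILES and scaffold label."""

    component_id: str
    smiles: str
    scaffold: str | None = None


@dataclass
class SimilarityMatrix:
    ids: list[str]
    values: np.ndarray  # square, symmetric, unit diagonal

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("similarity matrix shape mismatch")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _mol(entry: CompoundEntry):
    from rdkit import Chem

    mol = Chem.MolFromSmiles(entry.smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for compound "
                         f"{entry.component_id!r}: {entry.smiles!r}")
    return mol


def murcko_scaffold(smiles: str) -> str:
    """Bemis-Murcko framework SMILES (automatic scaffold fallback)."""
    from rdkit import Chem
    from rdkit.Chem.Scaffolds import MurckoScaffold

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    core = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(core)


def similarity_matrix(compounds: list[CompoundEntry]) -> SimilarityMatrix:
    """Pairwise Tanimoto similarity on 2D substructure fingerprints.

    Uses RDKit path-based fingerprints; the matrix is symmetric with a
    unit diagonal.  An unparseable SMILES raises a ``ValueError`` naming
    the offending compound.
    """
    from rdkit.Chem import RDKFingerprint
    from rdkit.DataStructs import TanimotoSimilarity

    ids = [c.component_id for c in compounds]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids")
    fps = [RDKFingerprint(_mol(c)) for c in compounds]
    n = len(fps)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = TanimotoSimilarity(fps[i], fps[j])
    return SimilarityMatrix(ids=ids, values=m)


def cluster_within_scaffolds(matrix: SimilarityMatrix,
                             scaffolds: dict[str, str],
                             ) -> tuple[list[str], dict[str, object]]:
    """Group compounds by scaffold; order each group by clustering.

    Within each scaffold group, average-linkage hierarchical clustering
    is run on the distance ``1 - similarity`` and compounds are returned
    in dendrogram leaf order.  Groups appear in ascending scaffold-label
    order; input permutation does not change the result (compounds are
    canonicalized by id before clustering).

    Returns the ordered compound list and a per-scaffold mapping to the
    scipy linkage matrix (``None`` for singleton groups).
    """
    from scipy.cluster.hierarchy import leaves_list, linkage
    from scipy.spatial.distance import squareform

    missing = [i for i in matrix.ids if i not in scaffolds]
    if missing:
        raise ValueError(f"compounds without scaffold label: {missing}")

    frame = matrix.to_frame()
    groups: dict[str, list[str]] = {}
    for cid in matrix.ids:
        groups.setdefault(scaffolds[cid], []).append(cid)

    ordered: list[str] = []
    dendrograms: dict[str, object] = {}
    for label in sorted(groups):
        members = sorted(groups[label])
        if len(members) == 1:
            ordered.extend(members)
            dendrograms[label] = None
            continue
        sub = frame.loc[members, members].to_numpy()
        dist = 1.0 - sub
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        z = linkage(squareform(dist, checks=False), method="average")
        order = leaves_list(z)
        ordered.extend(members[i] for i in order)
        dendrograms[label] = z
    return ordered, dendrograms


# ---------------------------------------------------------------------------
# repositioning evidence matrix


@dataclass
class EvidenceMatrix:
    """Drug-class by target-superfamily evidence grid."""

    rows: list[str]       # compound classes
    columns: list[str]    # target superfamilies
    cells: pd.DataFrame   # values in {"none", "structural", "other"}
    #: raw (compound, target, kind) pair mappings behind the aggregation
    pairs: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.rows) * len(self.columns)

    def to_tsv(self) -> str:
        return self.cells.to_csv(sep="\t")


@dataclass(frozen=True)
class CoverageStats:
    n_total: int
    n_structural: int
    n_other: int
    pct_structural: float
    pct_other: float
    pct_combined: float

    def rounded(self) -> dict:
        """Percentages to one decimal and to the nearest integer."""
        return {
            "pct_structural": (round(self.pct_structural, 1),
                               round(self.pct_structural)),
            "pct_other": (round(self.pct_other, 1), round(self.pct_other)),
            "pct_combined": (round(self.pct_combined, 1),
                             round(self.pct_combined)),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        return json.dumps({
            "n_total": self.n_total, "n_structural": self.n_structural,
            "n_other": self.n_other,
            "pct_structural": round(self.pct_structural, 1),
            "pct_other": round(self.pct_other, 1),
            "pct_combined": round(self.pct_combined, 1),
        }, **kwargs)


def build_evidence_matrix(pairs: list[tuple[str, str, str]],
                          compound_classes: dict[str, str],
                          target_superfamilies: dict[str, str],
                          ) -> EvidenceMatrix:
    """Aggregate compound-target evidence onto class/superfamily cells.

    Each raw pair is ``(compound, target, kind)`` with kind
    ``"structural"`` or ``"other"``.  A cell is ``structural`` when any
    mapped pair carries structural evidence (structural dominates),
    ``other`` when only other evidence exists, else ``none``.  The grid
    spans every class and superfamily present in the mappings, so
    evidence-free cells are explicit.
    """
    unmapped = sorted(
        {c for c, _, _ in pairs if c not in compound_classes}
        | {t for _, t, _ in pairs if t not in target_superfamilies})
    if unmapped:
        raise ValueError(f"unmapped compound/target ids: {unmapped}")
    bad = sorted({k for _, _, k in pairs if k not in EVIDENCE_KINDS})
    if bad:
        raise ValueError(f"unknown evidence kinds: {bad}; "
                         f"expected one of {EVIDENCE_KINDS}")

    rows = sorted(set(compound_classes.values()))
    cols = sorted(set(target_superfamilies.values()))
    cells = pd.DataFrame("none", index=rows, columns=cols)
    for comp, targ, kind in pairs:
        r = compound_classes[comp]
        c = target_superfamilies[targ]
        if kind == "structural" or cells.at[r, c] == "none":
            cells.at[r, c] = kind
    return EvidenceMatrix(rows=rows, columns=cols, cells=cells,
                          pairs=list(pairs))


def coverage_stats(matrix: EvidenceMatrix) -> CoverageStats:
    """Coverage percentages of the evidence matrix.

    Because structural evidence dominates within a cell, the structural
    and other percentages are disjoint and sum to the combined value.
    """
    n = matrix.n_cells
    if n == 0:
        raise ValueError("empty evidence matrix")
    vals = matrix.cells.to_numpy()
    n_struct = int((vals == "structural").sum())
    n_other = int((vals == "other").sum())
    return CoverageStats(
        n_total=n, n_structural=n_struct, n_other=n_other,
        pct_structural=100.0 * n_struct / n,
        pct_other=100.0 * n_other / n,
        pct_combined=100.0 * (n_struct + n_other) / n)
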