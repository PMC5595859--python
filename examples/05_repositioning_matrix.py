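"""Build a repositioning evidence matrix and its coverage statistics.

Aggregates compound-target binding evidence onto drug-class by
target-superfamily cells: structural evidence (crystal structures)
dominates over evidence from assays, pathways or text mining.
"""

from ipscreen import build_evidence_matrix, coverage_stats

compound_classes = {
    "BVD": "nucleosides", "THM": "nucleosides",
    "AQ4": "quinolines", "CHY": "flavones",
}
target_superfamilies = {
    "TK1": "P-loop NTP hydrolases", "HN1": "methyltransferases",
    "GP1": "glycosyltransferases",
}
pairs = [
    ("BVD", "TK1", "structural"),
    ("THM", "TK1", "structural"),
    ("THM", "TK1", "other"),        # structural dominates in this cell
    ("AQ4", "HN1", "structural"),
    ("AQ4", "TK1", "other"),
    ("CHY", "GP1", "structural"),
]

matrix = build_evidence_matrix(pairs, compound_classes, target_superfamilies)
print(matrix.cells.to_string())
stats = coverage_stats(matrix)
print(f"\n{stats.n_total} cells: {stats.n_structural} structural, "
      f"{stats.n_other} other")
print(f"coverage: {stats.pct_structural:.1f}% structural + "
      f"{stats.pct_other:.1f}% other = {stats.pct_combined:.1f}% combined")

# Green/orange-style coverage: each cell reports the strongest kind of
# binding evidence linking a drug class to a target superfamily; the
# combined percentage is the fraction of class/superfamily pairs with
# any support.
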