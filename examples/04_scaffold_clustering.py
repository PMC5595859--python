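"""Scaffold-aware chemical-similarity clustering of screen hits.

Computes pairwise fingerprint Tanimoto similarity for a small compound
panel, groups compounds by scaffold label and orders each group by
average-linkage clustering; this is how structurally novel hits are
separated from trivial analogues of the query drug.
"""

from ipscreen import (CompoundEntry, cluster_within_scaffolds,
                      murcko_scaffold, similarity_matrix)

compounds = [
    CompoundEntry("THM", "Cc1cn(C2CC(O)C(CO)O2)c(=O)[nH]c1=O",
                  scaffold="nucleoside"),   # thymidine
    CompoundEntry("DUR", "OCC1OC(n2ccc(=O)[nH]c2=O)CC1O",
                  scaffold="nucleoside"),   # deoxyuridine
    CompoundEntry("CAF", "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
                  scaffold="purine"),       # caffeine
    CompoundEntry("ADE", "Nc1ncnc2[nH]cnc12", scaffold="purine"),  # adenine
    CompoundEntry("QUE", "Oc1cc(O)c2c(c1)oc(-c1ccc(O)c(O)c1)c(O)c2=O",
                  scaffold="flavone"),      # quercetin
    CompoundEntry("CHY", "Oc1cc(O)c2c(c1)oc(-c1ccccc1)cc2=O",
                  scaffold="flavone"),      # chrysin
]

matrix = similarity_matrix(compounds)
order, dendrograms = cluster_within_scaffolds(
    matrix, {c.component_id: c.scaffold for c in compounds})

print("pairwise Tanimoto similarity:")
print(matrix.to_frame().round(2).to_string())
print("clustered order (scaffold groups contiguous):", order)
print("auto-scaffold of chrysin:", murcko_scaffold(
    next(c.smiles for c in compounds if c.component_id == "CHY")))

# Compounds sharing a scaffold stay adjacent; within a scaffold the
# most similar pair is placed together first, mirroring how heatmap
# axes are ordered when hunting for scaffold-hopping candidates.
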