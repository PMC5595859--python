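# ipscreen

Interaction-pattern screening of protein–ligand complexes for drug
repositioning.

`ipscreen` detects the noncovalent interactions of a bound ligand in a
3D structure — hydrogen bonds, hydrophobic contacts, π-stacking and
halogen bonds — and evaluates ten *interaction patterns* (A–J) derived
from how the antiviral nucleoside brivudine (BVDU) binds its kinase
targets. Ranking the ligands of a structure collection by how many of
these patterns they realize surfaces compounds that bind *like* the
query drug while being chemically unrelated to it (scaffold hopping),
which is the basis of an interaction-based repositioning screen.

It is a library: you use it from Python (see `examples/`), not from a
shell.

## The ten patterns

All patterns are defined relative to one **base ring**: a ligand
aromatic ring engaged in at least one π-stacking interaction.

| Pattern | Definition | Extra geometric constraint |
|---|---|---|
| A | aromatic ligand ring with π-stacking | — (prerequisite for all others) |
| B | double π-stacking to the base ring | two distinct protein rings |
| C | … on opposite faces | opposite face signs along the ring normal |
| D | … in parallel type | ≥ 2 face-to-face stacks |
| E | double hydrogen bonds on the ring moiety | ≥ 2 bonds anchored on ring ± one bond |
| F | … to a shared protein residue | both bonds to one residue |
| G | … in parallel | donor→acceptor vectors at 180° ± 18° |
| H | distal hydrophobic contact | anchor at 4.0 Å < x < 6.5 Å from ring centroid |
| I | distal hydrogen bond | anchor at 5.4 Å < x < 6.1 Å |
| J | distal halogen bond | halogen at 7.8 Å < x < 9.2 Å |

The distal bands use strict inequalities; detection thresholds for the
underlying interactions follow the documented defaults of the PLIP
profiler (hydrogen bond D–A ≤ 4.1 Å, hydrophobic ≤ 4.0 Å, stack
centroids ≤ 5.5 Å with ≤ 2.0 Å offset, halogen ≤ 4.0 Å with directional
windows) and are configurable via `DetectionConfig` / `PatternConfig`.

The per-complex score is the pattern count of the best single base
ring; per ligand, the best-scoring complex across the collection is
kept. Ligands with ≥ 6 patterns are reported as hits.

## Worked example

Evaluating a complex that realizes the pattern combination of the
repositioning hit amodiaquine (`examples/02_evaluate_patterns.py`):

```
pattern flags (base ring (19, 20, 21, 22, 23, 24) ):
  A [x]  e.g. {'protein_ring': [1, 2, 3, 4, 5, 6], 'distance': 3.5, 'type': 'parallel', 'face_sign': 1}
  B [x]  ...
  C [x]  ...
  D [x]  ...
  E [.]
  F [.]
  G [.]
  H [x]  e.g. {'ligand': 27, 'protein': 13, 'x': 5.25}
  I [.]
  J [x]  e.g. {'halogen': 35, 'acceptor': 17, 'x': 8.5}
pattern count: 6 / 10
```

The ligand stacks on both faces of its base ring (A–D), has a
hydrophobic anchor at 5.25 Å and a halogen at 8.5 Å from the ring
centroid (H, J), but lacks the paired hydrogen bonds (E–G) typical of
nucleoside binders — six patterns in total, which clears the hit
threshold.

Screening a 201-structure synthetic library
(`examples/03_screen_library.py`) prints a ranked table:

```
rank  component_id  best_count  A B C D E F G H I J  best_structure     n_complexes  drug_status
1     L5K           10          1 1 1 1 1 1 1 1 1 1  FX0200_ABCDEFGHIJ  1            none
2     L5D           9           1 1 1 1 1 1 1 1 1 0  FX0193_ABCDEFGHI   1            none
...
hits with >= 6 patterns: 111 (1 approved)
```

## What is in the package

* `ipscreen.structure_io` — PDB/mmCIF parsing (via biotite), covalent
  bond inference, ligand selection with a BioLiP-style allowlist,
  binding-site carving, aromatic-ring perception, atom typing.
* `ipscreen.interactions` — the four interaction detectors with full
  geometric attributes and JSON serialization.
* `ipscreen.patterns` — pattern evaluation per base ring, evidence
  recording, best-ring selection.
* `ipscreen.screening` — collection screening, best-complex
  aggregation, ranking, drug-status annotation, TSV/JSON reports.
* `ipscreen.prioritization` — fingerprint Tanimoto similarity,
  scaffold-aware average-linkage clustering, repositioning evidence
  matrix with coverage statistics.
* `ipscreen.fixtures` — deterministic synthetic binding sites realizing
  any implication-closed pattern subset, self-checked through the full
  pipeline; the ground truth for the test suite.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computations from
scratch: it rebuilds and re-evaluates a fixture for every
implication-closed pattern subset, screens a fresh 100-structure
library end to end (recovering the planted pattern counts, ranking and
hit census), and recomputes the evidence-matrix coverage arithmetic.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Limitations

Heavy-atom operation: explicit hydrogens are used when present but
donor capability is otherwise inferred from element, connectivity and
bond lengths, so borderline hydrogen bonds may differ from profilers
that protonate internally. See `docs/methods.md` for the full model
description and numerical choices.
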