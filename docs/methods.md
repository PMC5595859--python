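# Methods

This note documents the models and procedures implemented in
`ipscreen`, the defaults and why they were chosen, what the synthetic
fixtures do and do not establish, and the numerical choices made where
the design was genuinely open.

## Structure handling

Structures are read from PDB or mmCIF through biotite. Only the first
model of multi-model files is used; alternate locations are resolved to
the highest-occupancy conformer (ties keep the first conformer in file
order, conventionally altloc A). Residue numbering is taken verbatim.

**Covalent bonds** are inferred from interatomic distances: two atoms
are bonded when their distance is at most the sum of their covalent
radii (Cordero consensus values) plus 0.45 Å slack, and above 0.4 Å.
CONECT records, when present, supplement the inferred set. The slack
value is the common choice that keeps standard bond lengths inside the
rule while excluding 1–3 neighbor distances (shortest relevant gap:
carbon pairs become bonded below 1.97 Å).

**Binding sites** are carved around each ligand instance (hetero
residue that is not water, optionally restricted by a user-supplied
BioLiP-style allowlist: the biological-relevance decision is consumed,
never recomputed). Protein atoms within 7.5 Å of any ligand atom form
the site; 7.5 Å matches the reference profiler's documented default.
Residues partially inside the cutoff are completed for ring perception
and neighbor geometry so rings straddling the boundary are not
truncated, but the site membership itself is strictly the cutoff rule.

**Aromatic rings** are the minimum cycle basis of the bond graph
restricted to C/N/O/S, filtered to sizes 5–6 and planarity ≤ 0.15 Å
(maximum deviation from the best-fit plane). The tolerance covers
nucleobases, phenyl and imidazole while rejecting puckered cyclohexane
(±0.25 Å chair). The ring normal is the smallest-covariance
eigenvector, sign-canonicalized (positive z, ties broken toward +x) so
that face assignments are deterministic; under a global rigid motion
the canonical sign may flip as a whole, which leaves all pairwise face
comparisons (pattern C) invariant.

**Atom typing** is heavy-atom based. Explicit hydrogens decide donor
status when present; otherwise donors are inferred:

* O with one heavy neighbor: carbonyl-like below a 1.30 Å bond
  (acceptor only), hydroxyl-like above it (donor + acceptor); ethers
  accept only; bare O (water-like) donates and accepts.
* N in an aromatic ring with two heavy neighbors and no H:
  pyridine-like acceptor. Non-ring N with ≤ 2 heavy neighbors: donor
  (an attachable H is implied); a single very short bond (< 1.25 Å,
  nitrile/imine-like) makes it an acceptor instead.
* Hydrophobic: carbon whose heavy neighbors are all carbon.
* Halogen: Cl, Br, I; fluorine is excluded by default (negligible
  σ-hole) and can be enabled in `DetectionConfig`.

This substitutes for the internal protonation step of PLIP-style
profilers. On marginal geometries (e.g. histidine tautomers, borderline
donor angles) the surrogate can disagree with a protonation engine;
that is a documented limitation, not a tunable.

## Interaction detection

Thresholds are inclusive and configurable; defaults mirror the
reference profiler's documented settings.

* **Hydrogen bonds**: donor–acceptor heavy-atom distance ≤ 4.1 Å, both
  directions across the interface. With explicit H the largest D–H⋯A
  angle must be ≥ 100°; without H the surrogate is the smallest
  neighbor–D⋯A angle, required ≥ 90° (donors without neighbors pass
  trivially). The same atom pair is reported once, preferring the
  ligand-donor direction.
* **Hydrophobic contacts**: hydrophobic-carbon pairs ≤ 4.0 Å; per
  ligand atom only the nearest protein partner is kept, which curbs
  contact inflation in packed apolar pockets. On exact distance ties
  the partner with the lower serial is kept; partner identity on ties
  is the one detection detail that is not rigid-motion stable (the
  distance is).
* **π-stacking**: ring-pair centroid distance ≤ 5.5 Å, lateral offset
  (in-plane component of the centroid displacement w.r.t. the ligand
  ring) ≤ 2.0 Å, interplanar angle ≤ 30° (parallel) or 60–90°
  (T-shaped). `face_sign` records the side of the ligand-ring plane
  holding the protein centroid; exactly in-plane centroids (|axial
  component| < 1e-9) are discarded rather than assigned a face.
* **Halogen bonds**: ligand Cl/Br/I with a carbon neighbor versus
  protein O/N/S; distance ≤ 4.0 Å, C–X⋯A angle within 165° ± 30°, and
  (when the acceptor has heavy neighbors) some Y–A⋯X angle within
  120° ± 30°.

Detections are ordered canonically (ligand serial, then protein
serial), making profiles deterministic for identical input and
configuration.

## Pattern evaluation

Patterns are evaluated per candidate base ring (a stacked ligand ring);
the complex-level result is the best single ring, ties broken toward
the ring earliest in canonical atom order. No union across rings is
taken: every pattern is defined relative to one base ring.

Open choices resolved here:

* **Distal distance x** is measured from the ligand-side anchor atom
  (hydrophobic carbon, hydrogen-bond ligand anchor, halogen) to the
  base-ring centroid. The centroid is unambiguous and symmetric; the
  alternative (nearest ring atom) would shift borderline hits by up to
  one ring radius.
* **Ring moiety** for patterns E–G is the ring members plus atoms
  covalently bonded to a member, capturing the exocyclic carbonyl O and
  amino N of nucleobases.
* **Pattern G** uses directed donor→acceptor unit vectors; a pair
  qualifies when the angle between them is within 180° ± 18°, i.e. the
  bonds run antiparallel, as they do when the ligand donates one bond
  and accepts the other across the same edge.
* **Distal bands** are strict inequalities: an anchor exactly on a
  boundary does not qualify, unlike the inclusive detection thresholds.
  The band constants and the G window are the published constraints and
  live in `PatternConfig`.

The implications B⇒A, C⇒B, D⇒B, E⇒A, F⇒E, G⇒E, H⇒A, I⇒A, J⇒A hold by
construction; they are nonetheless fuzz-tested on random profiles.

## Screening and prioritization

Per ligand component, the complex with the highest pattern count wins
(ties: lexicographically smallest structure id, then chain and residue
number). Ranking sorts by count descending with component-id
tie-breaks; the default hit threshold is six patterns. Per-structure
failures during a collection screen are logged and skipped so one
corrupt file cannot kill a large run; a screen with zero readable
structures is an error.

Chemical similarity uses RDKit path-based 2D fingerprints with Tanimoto
scoring — a local, reproducible substitute for a remote score-matrix
service; absolute values differ from other fingerprints, so only
orderings and groupings are asserted, not specific similarity values.
Compounds are grouped by user-supplied scaffold labels (with a
Bemis–Murcko framework fallback) and ordered within each group by
average-linkage hierarchical clustering on 1 − similarity, canonicalized
by compound id so input order cannot change the result.

The repositioning evidence matrix aggregates raw (compound, target,
kind) pairs onto drug-class × target-superfamily cells; structural
evidence dominates "other" evidence within a cell, which makes the two
coverage percentages disjoint and additive. Percentages are reported
over all cells of the full class × superfamily grid, including
evidence-free ones.

## Synthetic fixtures: what they establish

The fixture generator emulates a binding site, not chemistry: a planar
carbon hexagon ligand with substituent arms, protein partners written
as plausible residues (PHE rings, GLN/ASN amides, LEU carbons, a
backbone carbonyl) at controlled geometry. Every requested
implication-closed pattern subset is realized exactly, verified by
running the generated structure through the package's own parse →
profile → evaluate pipeline at build time; a fixture that fails this
self-check refuses to build.

Placement choices worth knowing:

* distal anchors sit at band midpoints (5.25 / 5.75 / 8.5 Å) with
  optional jitter up to ±0.2 Å, keeping ≥ 0.1 Å margin to the strict
  band bounds; negative probes sit ≥ 0.4 Å outside their band so the
  strict inequalities are genuinely exercised;
* stack placements (3.2–5.4 Å, parallel or perpendicular) were chosen
  so that no inter-residue distance falls below the bond-inference
  cutoff — accidental covalent bonds between stacked rings would merge
  their ring systems;
* incidental hydrophobic contacts between the ligand ring and stacked
  PHE carbons do occur (as they would in a real pocket) but at
  anchor-to-centroid distances below 4.0 Å, outside the H band.

A green fixture round-trip establishes that detection geometry,
pattern logic, aggregation and ranking are internally consistent and
exact on controlled input. It does not establish agreement with any
historical full-database screen: those censuses depend on a database
snapshot, the profiler's protonation engine and its exact thresholds,
none of which are reproducible offline. Real-structure behavior on
borderline geometries may differ within the documented threshold
semantics.

## Determinism and seeds

All randomness (fixture jitter, rigid motions, library generation)
flows through `numpy.random.default_rng` seeds carried in
`FixtureSpec`/function arguments; identical seeds give byte-identical
PDB output. Coordinates are written at PDB precision (0.001 Å), three
orders of magnitude below every geometric margin used.
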