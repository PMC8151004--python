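# Methods

## Data model and scoring

A corpus is an ordered set of documents, each a bag of acupuncture-point
(AP) mentions labeled by textbook (style) and disease. AP codes use the
14-meridian nomenclature (LU, LI, ST, SP, HT, SI, BL, KI, PC, TE, GB, LR,
GV, CV with their standard point ranges, 361 codes in all); `TB` is
accepted on input as an alias for TE. The vocabulary is ordered by
meridian enumeration order then point number so matrix columns are
bit-for-bit reproducible.

The AP-score of a document is its relative-frequency vector over the
vocabulary. Mentions count with multiplicity by default — a point selected
six times contributes six — because prescription frequency is part of the
signal; a `binary=True` mode (each distinct point once) is available for
sensitivity analysis.

Four attribute scores condense each document to the fraction of its
mention instances carrying a theoretical attribute, in the fixed column
order (distant, extra_meridian, five_transport, source):

* **extra_meridian** — the point lies on the governor or conception
  vessel, decidable from the code alone;
* **five_transport** — the point is one of the 60 well/brook/stream/
  river/sea points (5 per regular meridian), all distal to elbow/knee;
* **source** — one of the 12 source points (on yin meridians these
  coincide with the stream points, so source ∩ five_transport has six
  members — an overlap that matters for interpretation, see Limitations);
* **distant** — "far from the disease site" has no canonical
  operationalization, so the rule is pluggable: the default
  `region_heuristic` marks a point distant iff its body region is
  distal_limb while the disease's annotated site region is not;
  an explicit per-(disease, point) table and a disabled mode (score
  identically 0) are alternatives.

The packaged reference table annotates all 361 codes with these flags plus
a four-class body region (distal_limb, proximal_limb, head, trunk — the
minimum a distant rule needs). It follows the WHO standard acupuncture
nomenclature and is validated on load: exactly 12 source points, exactly
60 transport points all in distal_limb, extra-meridian flags exactly on
GV/CV, yin source = stream.

## The permutation test

For a grouping (textbook or disease) the statistic is the mean Euclidean
distance over same-label document pairs. The null is estimated by B
uniform random permutations of the label vector (multiplicity-preserving,
sampled with replacement), recomputing the statistic on the fixed distance
matrix; since the distances never change, each draw costs O(pairs) and the
implementation vectorizes draws in batches of 10⁵ (results are independent
of batching). The test is left-tailed (smaller distance = more similar),
p = #{null ≤ observed}/B, reported as "<1/B" when the count is zero; ties
with the observed value count as ≤, which is conservative. A conservative
(k+1)/(B+1) convention is available by flag. When n! ≤ B the test switches
to exhaustive enumeration of all label permutations and the p-value is
exact. Default B = 10⁵, configurable.

Whether to permute within the disease-stratified design or fully at random
is an open choice; fully random permutation is used, matching the
statistic's exchangeability null. The similarity suite runs same-textbook
and same-disease tests for the full corpus and each textbook pair
(2 + 2·C(T,2) tests; 8 for three textbooks) and applies Benjamini–Hochberg
correction jointly across the suite (statsmodels `fdr_bh`).

## Structural views

* **Hierarchical clustering**: scipy agglomerative linkage on the
  precomputed distances; default average linkage (complete and ward are
  exposed; ward is valid because all distances here are Euclidean).
* **MDS**: metric stress minimization (SMACOF) warm-started at the
  classical Torgerson solution with 7 additional random restarts, best
  stress kept; seed-controlled. Exactly planar configurations therefore
  reach stress at machine precision. A pure `classical` mode is available.
* **SVM separability**: an RBF-kernel SVM (C = 10, γ = 1) fit on the 2-D
  coordinates; the F1 of its in-sample predictions describes how cleanly a
  boundary separates two groups in the plane. This is descriptive, not a
  generalization estimate, and is documented as such.
* **Similarity networks**: retain the round(s·C(n,2)) smallest-distance
  pairs at sparsity s (at least one edge for any s > 0; ties at the cutoff
  break lexicographically), yielding nested edge sets across the default
  sweep {0.02, 0.05, 0.10, 0.20}. The within-group edge fraction for each
  grouping summarizes which structure survives strict thresholds.

## Attribution

Repeated random forests (default 500 trees × 50 repeats with seeds derived
from one root seed) classify a binary style contrast from the four
attribute scores; the contribution score of an attribute is its mean
normalized impurity-decrease importance, with the across-repeat sd as a
stability measure (permutation importance available by flag). A constant
feature matrix makes importances undefined; uniform scores are returned
with a warning flag rather than an error.

Per-attribute enrichment between two textbooks uses the two-sided Wilcoxon
signed-rank test on the per-disease paired differences (disease is the
only alignment key in the design), exact for small samples without ties,
normal approximation with continuity correction otherwise, zeros dropped;
BH correction across the four attributes, starring adjusted p < 0.01. An
unpaired Mann–Whitney mode exists but is off by default.

## Synthetic corpora

The generator emulates the structured-record level of the study design:
one document per textbook × disease cell (defaults 3 × 14 = 42 documents,
30 mentions each). Per corpus, a baseline distribution b over the 361
codes is drawn Dirichlet(0.5); document (t, d) samples mentions
multinomially with weights

```
w_a ∝ b_a · (1 + s·1[a carries preferred_attribute(t)]) · (1 + g·1[a ∈ signature(d)])
```

Multiplicative (1 + strength·indicator) tilting is bounded, interpretable,
and exactly null at strength 0, so s = g = 0 yields i.i.d. documents — the
permutation test's exchangeability null by construction. Default planted
preferences cycle five_transport / extra_meridian / source across
textbooks, mirroring the three classical styles the analysis was designed
around. Disease signatures are 8 points sampled uniformly without
replacement (disjointness not enforced; real diseases share points), and
each disease is assigned a site region cycling head/trunk/proximal_limb so
the region-heuristic distant rule is resolvable.

Because an attribute set covers 52–60 of 361 points while a disease
signature covers 8, equal numeric strengths are not equal signals: the
expected baseline mass tilted by a style preference (~14–17%) is roughly
seven times that tilted by a signature (~2.2%). Power studies of
disease-driven structure therefore use g ≈ 10, the strength at which the
planted absolute mass shift matches a style effect of s = 2.

What the generator does *not* emulate: real prescriptions are not
multinomial draws (points co-occur in formula-like combinations),
textbooks differ in document length and vocabulary breadth, and disease
effects in real corpora act through shared specific points with large
mass, not uniformly chosen signatures. Passing recovery tests on this
generator shows the machinery detects the planted effect classes at the
stated strengths; it does not certify effect sizes on real corpora.

## Problem sizes and numerical choices

Calibration and power studies in the test suite use B = 2000 null draws
per test, 50–200 replicates, and forests of 100 trees × 5 repeats — sizes
at which every reported rate has a Monte-Carlo standard error comfortably
below the decision margins while a full run stays in a coffee break.
Distances are computed once per suite entry; tie handling, the ≤
convention and seed derivation (numpy `SeedSequence`, children kept below
2³¹) are fixed so identical inputs give identical outputs everywhere,
including the CLI pipeline whose manifest hashes every output file.

## Known limitations

* The source attribute is small (12 points) and half-overlapping with the
  five-transport set, so in one-vs-rest contrasts among three styles the
  *absence* of the other styles' attributes discriminates about as well as
  the source score itself; contribution scores spread accordingly at
  moderate effect strength. The pairwise contrast and the signed-rank
  tests are the sharper instruments for source-point preference.
* The region annotation is deliberately coarse (four classes per point,
  assigned by point-number runs along each meridian); distant-point scores
  inherit that coarseness.
* The permutation test treats documents as exchangeable under the null;
  design-stratified permutation is not implemented.
* F1 separability is in-sample by design and should not be read as
  classifier performance.
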