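# apstyle

Quantifying how much acupuncture-point (AP) prescriptions differ by
*acupuncture style* versus by *disease*, and explaining style differences
through the theoretical attributes of the selected points.

Traditional acupuncture textbooks prescribe sets of points, with
repetition, for each disease they cover. Different clinical traditions
("styles") select points according to different theoretical frameworks —
some favour the *five transport points* on the limbs, some the points of
the *governor and conception vessels* (the extra meridians), some the
*source points* associated with original qi. `apstyle` turns a corpus of
such prescriptions into document-level frequency profiles and asks, with a
permutation test, whether documents from the same textbook resemble each
other more than chance, whether documents treating the same disease do,
and — via random-forest contribution scores over four attribute scores —
which theoretical attribute carries each style's signature.

## The model

Each document *i* (one textbook chapter, a bag of AP mentions) becomes an
**AP-score** vector: `x_ij = c_ij / Σ_j c_ij`, the relative frequency of
point *j* among the document's mentions (rows sum to 1). An **AP
attribute-score** matrix condenses the same counts into the fraction of
mentions carrying each of four attributes: *distant*, *extra meridian*,
*five transport*, *source*.

Similarity is the Euclidean distance `d(i, k) = ‖x_i − x_k‖₂` (smaller =
more similar). The test statistic for a grouping (textbook or disease) is
the **mean distance over all same-label document pairs**. Its null
distribution is estimated empirically by drawing B uniform permutations of
the label vector and recomputing the statistic on the fixed distance
matrix; the empirical p-value is the left-tail fraction

```
p = #{ null statistics ≤ observed } / B,       displayed "<1/B" when the count is 0,
```

with Benjamini–Hochberg correction across the suite of tests (all
textbooks and each textbook pair × both groupings, 8 tests for 3
textbooks). Hierarchical clustering, 2-D metric MDS with a descriptive
RBF-SVM separability F1 (C = 10, γ = 1), and nearest-pair similarity
networks at several sparsity levels give complementary structural views.
Style attribution fits repeated random forests on the attribute scores and
reports normalized feature importances ("contribution scores"), plus
per-attribute two-sided Wilcoxon signed-rank tests pairing the two
textbooks' documents by disease.

Because the corpora this analysis was designed for are not freely
redistributable, the package ships a generator of synthetic corpora with
the same design (3 textbooks × 14 diseases, one document per cell): a
Dirichlet baseline over the 361 standard APs, tilted multiplicatively by a
per-textbook preferred attribute (style strength *s*) and per-disease
signature point sets (disease strength *g*), with the planted truth
returned for calibration and recovery studies.

## Worked example

```python
import numpy as np
from apstyle import (SynthConfig, simulate_corpus, run_similarity_suite,
                     suite_to_frame, attribute_scores, default_attribute_table,
                     rf_contributions, wilcoxon_attribute_tests)

corpus, truth = simulate_corpus(SynthConfig(style_strength=2.0, seed=7))
suite = run_similarity_suite(corpus, B=100_000, seed=0)
print(suite_to_frame(suite).round(4).to_string(index=False))
```

```
                           subset      grouping  observed  expected p_display  p_adjusted stars
textbook1 + textbook2 + textbook3 same textbook    0.2567    0.2589   0.00095      0.0076     *
textbook1 + textbook2 + textbook3  same disease    0.2583    0.2589     0.374      0.5057
            textbook1 + textbook2 same textbook    0.2573    0.2595   0.00426      0.0170     *
            textbook1 + textbook2  same disease    0.2595    0.2595      0.49      0.5057
            textbook1 + textbook3 same textbook    0.2560    0.2569    0.0784      0.1567
            textbook1 + textbook3  same disease    0.2567    0.2569     0.463      0.5057
            textbook2 + textbook3 same textbook    0.2568    0.2586   0.00914      0.0244     *
            textbook2 + textbook3  same disease    0.2588    0.2586     0.506      0.5057
```

The planted style effect (s = 2) pulls the observed same-textbook mean
distance below its null expectation (0.2567 vs 0.2589, adjusted p ≈ 0.008)
while the same-disease tests stay null — the corpus is more homogeneous
within textbooks than within diseases. Attribution recovers what was
planted:

```python
X = attribute_scores(corpus, default_attribute_table())
tb = np.array(corpus.labels("textbook"))
rep = rf_contributions(X, (tb == "textbook1").astype(int), seed=0)
print(rep.scores.round(3))
w = wilcoxon_attribute_tests(X, tb, corpus.labels("disease"),
                             "textbook2", "textbook3")
print(w.table.round(4))
```

```
                 mean     sd
distant         0.000  0.000
extra_meridian  0.230  0.007
five_transport  0.674  0.008
source          0.096  0.004

                statistic       p            direction   p_adj star
attribute
distant               0.0  1.0000  textbook3>textbook2  1.0000
extra_meridian        2.0  0.0017  textbook2>textbook3  0.0043   **
five_transport       32.0  0.3627  textbook3>textbook2  0.4836
source                0.0  0.0022  textbook3>textbook2  0.0043   **
```

The forest contrasting textbook1 with the rest puts 67% of the
contribution on *five transport* — textbook1's planted preference — and
the paired signed-rank tests flag *extra meridian* enriched in textbook2
and *source* in textbook3, each at BH-adjusted p < 0.01.

The same analysis runs from the shell:

```bash
apstyle simulate --seed 7 --style-strength 2 --out demo
apstyle run demo/corpus.csv --seed 0 -B 100000 --out demo_results
```

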