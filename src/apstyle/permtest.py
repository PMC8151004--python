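"""Label-permutation test for within-group prescription similarity.

The statistic is the mean Euclidean distance between score rows of
documents sharing a label (same textbook, or same disease): smaller
distance means greater within-group similarity.  The null distribution is
estimated empirically by uniformly permuting the label vector (preserving
label multiplicities) and recomputing the statistic on the fixed distance
matrix; the test is left-tailed, with empirical p = #{null <= observed}/B
and the display convention "<1/B" when no null draw is as small as the
observed value.  Benjamini-Hochberg correction is applied jointly across a
suite of such tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .corpus_io import Corpus
from .scoring import ap_scores

__all__ = [
    "pairwise_distances",
    "same_label_mean_distance",
    "PermTestResult",
    "permutation_test",
    "run_similarity_suite",
    "bh_adjust",
    "suite_to_frame",
]

_BATCH = 100_000  # null draws per vectorized batch; results batch-independent


def pairwise_distances(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Square symmetric Euclidean distance matrix between score rows."""
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.isfinite(values).all():
        raise ValueError("non-finite values in score matrix")
    dense = squareform(pdist(values, metric="euclidean"))
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(dense, index=matrix.index, columns=matrix.index)
    return pd.DataFrame(dense)


def _as_square(D) -> np.ndarray:
    arr = np.asarray(D, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    return arr


def _pair_mask(codes: np.ndarray) -> np.ndarray:
    return codes[:, None] == codes[None, :]


def same_label_mean_distance(D, labels) -> float:
    """Mean distance over unordered document pairs sharing a label."""
    arr = _as_square(D)
    codes = pd.factorize(np.asarray(labels))[0]
    if len(codes) != arr.shape[0]:
        raise ValueError("labels not aligned with distance matrix")
    mask = np.triu(_pair_mask(codes), k=1)
    n_pairs = int(mask.sum())
    if n_pairs == 0:
        raise ValueError("no pair of documents shares a label")
    return float(arr[mask].sum() / n_pairs)


@dataclass(frozen=True)
class PermTestResult:
    """Outcome of one permutation test (one row of the similarity suite)."""

    grouping: str                 # 'textbook' or 'disease'
    subset: tuple[str, ...]       # textbook labels included
    observed: float               # mean same-label distance
    expected: float               # mean of the null statistics
    p_empirical: float            # #{null <= observed} / B
    B: int
    seed: int | None
    null_sd: float = float("nan")  # sd of the null statistics
    exhaustive: bool = False
    p_adjusted: float | None = None  # BH across the suite; filled by the runner

    @property
    def p_display(self) -> str:
        if self.p_empirical == 0.0:
            return f"<{1.0 / self.B:.3g}"
        return f"{self.p_empirical:.3g}"


def _null_stats_monte_carlo(
    arr: np.ndarray, codes: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized null statistics for B uniform label permutations."""
    n = len(codes)
    # number of same-label pairs is permutation-invariant
    n_pairs = int(np.triu(_pair_mask(codes), k=1).sum())
    out = np.empty(B)
    done = 0
    while done < B:
        b = min(_BATCH, B - done)
        perms = rng.permuted(np.tile(codes, (b, 1)), axis=1)
        total = np.zeros(b)
        for v in np.unique(codes):
            x = (perms == v).astype(float)
            total += np.einsum("bi,bi->b", x @ arr, x)
        out[done : done + b] = total / (2.0 * n_pairs)
        done += b
    return out


def _null_stats_exhaustive(arr: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Null statistics for every permutation of the label vector."""
    n = len(codes)
    n_pairs = int(np.triu(_pair_mask(codes), k=1).sum())
    stats = []
    for perm in itertools.permutations(range(n)):
        c = codes[list(perm)]
        mask = np.triu(_pair_mask(c), k=1)
        stats.append(arr[mask].sum() / n_pairs)
    return np.asarray(stats)


def permutation_test(
    D,
    labels,
    B: int = 100_000,
    seed: int | None = None,
    *,
    grouping: str = "label",
    subset: tuple[str, ...] = (),
    mode: str = "auto",
    add_one: bool = False,
) -> PermTestResult:
    """Left-tailed label-permutation test of within-group similarity.

    Parameters
    ----------
    D : square distance matrix (array or DataFrame)
    labels : per-document label vector aligned with D's rows
    B : number of null permutations (Monte-Carlo, with replacement)
    seed : RNG seed; fixed seed gives identical results
    mode : 'monte_carlo', 'exhaustive', or 'auto' (exhaustive when n! <= B)
    add_one : use the conservative (k+1)/(B+1) p-value convention instead of
        the default k/B

    Ties (null statistic exactly equal to the observed) count as <=, which
    is conservative for a left-tailed test.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if mode not in ("auto", "monte_carlo", "exhaustive"):
        raise ValueError(f"unknown mode {mode!r}")
    arr = _as_square(D)
    label_arr = np.asarray(labels)
    if len(set(label_arr.tolist())) < 2:
        raise ValueError("labels are constant; the test is degenerate")
    codes = pd.factorize(label_arr)[0]
    observed = same_label_mean_distance(arr, label_arr)

    n = len(codes)
    exhaustive = mode == "exhaustive" or (
        mode == "auto" and math.factorial(n) <= B
    )
    if exhaustive:
        null = _null_stats_exhaustive(arr, codes)
    else:
        rng = np.random.default_rng(seed)
        null = _null_stats_monte_carlo(arr, codes, B, rng)

    k = int(np.sum(null <= observed + 1e-12))
    n_null = len(null)
    if add_one and not exhaustive:
        p = (k + 1) / (n_null + 1)
    else:
        p = k / n_null
    return PermTestResult(
        grouping=grouping,
        subset=tuple(subset),
        observed=observed,
        expected=float(null.mean()),
        p_empirical=float(p),
        B=n_null,
        seed=seed,
        null_sd=float(null.std()),
        exhaustive=exhaustive,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.ndim != 1 or len(arr) == 0:
        raise ValueError("pvalues must be a non-empty 1-D vector")
    if ((arr < 0) | (arr > 1)).any() or not np.isfinite(arr).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def run_similarity_suite(
    corpus: Corpus,
    B: int = 100_000,
    seed: int | None = None,
    *,
    scores: pd.DataFrame | None = None,
    mode: str = "auto",
    add_one: bool = False,
) -> list[PermTestResult]:
    """The full similarity test suite over a multi-textbook corpus.

    Runs the same-textbook and same-disease tests on AP-scores for the
    all-textbooks document set and for each textbook pair (documents
    restricted to the pair): 2 + 2*C(T,2) results for T textbooks (8 for
    T = 3).  BH adjustment is applied jointly across the suite.
    """
    textbooks = corpus.textbooks
    if len(textbooks) < 2 or len(corpus.diseases) < 2:
        raise ValueError("suite needs >= 2 textbooks and >= 2 diseases")

    subsets: list[tuple[str, ...]] = [tuple(textbooks)]
    subsets += [tuple(p) for p in itertools.combinations(textbooks, 2)]

    child_seeds = np.random.SeedSequence(seed).generate_state(2 * len(subsets))
    results: list[PermTestResult] = []
    i = 0
    for subset in subsets:
        sub = corpus if set(subset) == set(textbooks) else corpus.subset(subset)
        mat = ap_scores(sub) if scores is None else scores.loc[sub.doc_ids]
        D = pairwise_distances(mat)
        for grouping in ("textbook", "disease"):
            results.append(
                permutation_test(
                    D,
                    sub.labels(grouping),
                    B=B,
                    seed=int(child_seeds[i] % (2**31)),
                    grouping=grouping,
                    subset=subset,
                    mode=mode,
                    add_one=add_one,
                )
            )
            i += 1

    adjusted = bh_adjust([r.p_empirical for r in results])
    return [replace(r, p_adjusted=float(a)) for r, a in zip(results, adjusted)]


def _stars(p_adj: float) -> str:
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.05:
        return "*"
    if p_adj < 0.1:
        return "#"
    return ""


def suite_to_frame(results: list[PermTestResult]) -> pd.DataFrame:
    """Tabular view of a suite: one row per test, table-style columns."""
    rows = []
    for r in results:
        rows.append(
            {
                "subset": " + ".join(r.subset),
                "grouping": f"same {r.grouping}",
                "observed": r.observed,
                "expected": r.expected,
                "p_display": r.p_display,
                "p_adjusted": r.p_adjusted,
                "stars": _stars(r.p_adjusted) if r.p_adjusted is not None else "",
                "B": r.B,
                "seed": r.seed,
            }
        )
    return pd.DataFrame(rows)
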