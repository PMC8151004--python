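"""Attributing style differences to theoretical AP attributes.

Random-forest classifiers are trained to tell two document groups apart
from their four attribute scores; the normalized impurity-decrease feature
importances ("contribution scores") say which attribute carries the
separation.  Per-attribute paired Wilcoxon signed-rank tests (pairing
documents of two textbooks by disease) then test the direction and
significance of each attribute's enrichment, with Benjamini-Hochberg
correction across the four attributes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, wilcoxon
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .permtest import bh_adjust
from .scoring import ATTRIBUTES

__all__ = [
    "ContributionReport",
    "rf_contributions",
    "style_contrast_tasks",
    "AttributeTestReport",
    "wilcoxon_attribute_tests",
]


@dataclass(frozen=True)
class ContributionReport:
    """Mean +/- sd contribution score per attribute over repeated forests."""

    task: str
    scores: pd.DataFrame          # index attributes, columns mean/sd
    per_repeat: np.ndarray        # (n_repeats, n_attributes), each row sums to 1
    n_trees: int
    n_repeats: int
    seed: int | None
    degenerate: bool = False      # constant features; uniform scores returned

    def top_attribute(self) -> str:
        return str(self.scores["mean"].idxmax())

    def ranking(self) -> list[str]:
        return list(self.scores["mean"].sort_values(ascending=False).index)


def rf_contributions(
    X: pd.DataFrame,
    labels,
    n_trees: int = 500,
    n_repeats: int = 50,
    seed: int | None = None,
    *,
    task: str = "",
    importance: str = "impurity",
) -> ContributionReport:
    """Contribution scores of the attributes for a binary style contrast.

    Fits ``n_repeats`` forests with seeds derived from ``seed`` and averages
    the normalized feature importances; the sd across repeats is reported as
    a stability measure.  ``importance='permutation'`` swaps in permutation
    importances (renormalized to sum to 1, negatives clipped at 0).
    """
    if n_trees < 1 or n_repeats < 1:
        raise ValueError("n_trees and n_repeats must be >= 1")
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain exactly 2 classes")
    features = np.asarray(X, dtype=float)
    columns = list(X.columns) if isinstance(X, pd.DataFrame) else list(ATTRIBUTES)

    if np.allclose(features.std(axis=0), 0.0):
        warnings.warn(
            "constant feature matrix; contribution scores are undefined, "
            "returning uniform scores",
            RuntimeWarning,
        )
        uniform = np.full((n_repeats, features.shape[1]), 1.0 / features.shape[1])
        scores = pd.DataFrame(
            {"mean": uniform[0], "sd": np.zeros(features.shape[1])}, index=columns
        )
        return ContributionReport(task, scores, uniform, n_trees, n_repeats, seed, True)

    child_seeds = np.random.SeedSequence(seed).generate_state(n_repeats)
    per_repeat = np.empty((n_repeats, features.shape[1]))
    for r in range(n_repeats):
        forest = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(child_seeds[r] % (2**31))
        )
        forest.fit(features, y)
        if importance == "impurity":
            imp = forest.feature_importances_
        elif importance == "permutation":
            pi = permutation_importance(
                forest, features, y,
                n_repeats=10, random_state=int(child_seeds[r] % (2**31)),
            )
            imp = np.clip(pi.importances_mean, 0.0, None)
        else:
            raise ValueError(f"unknown importance mode {importance!r}")
        total = imp.sum()
        per_repeat[r] = imp / total if total > 0 else np.full_like(imp, 1 / len(imp))

    scores = pd.DataFrame(
        {"mean": per_repeat.mean(axis=0), "sd": per_repeat.std(axis=0)},
        index=columns,
    )
    return ContributionReport(task, scores, per_repeat, n_trees, n_repeats, seed)


def style_contrast_tasks(
    X: pd.DataFrame,
    textbooks,
    *,
    one_vs_rest: str | None = None,
    pair: tuple[str, str] | None = None,
    n_trees: int = 500,
    n_repeats: int = 50,
    seed: int | None = None,
) -> list[ContributionReport]:
    """The two style contrasts of interest as contribution reports.

    ``one_vs_rest`` contrasts one textbook against all others on the full
    matrix; ``pair`` restricts the documents to two textbooks and contrasts
    them.  Either or both may be requested.
    """
    tb = np.asarray(textbooks)
    reports = []
    if one_vs_rest is not None:
        y = (tb == one_vs_rest).astype(int)
        reports.append(
            rf_contributions(
                X, y, n_trees, n_repeats, seed,
                task=f"{one_vs_rest}_vs_rest",
            )
        )
    if pair is not None:
        a, b = pair
        keep = np.isin(tb, [a, b])
        y = (tb[keep] == a).astype(int)
        reports.append(
            rf_contributions(
                X.loc[keep] if isinstance(X, pd.DataFrame) else np.asarray(X)[keep],
                y, n_trees, n_repeats, seed,
                task=f"{a}_vs_{b}",
            )
        )
    return reports


@dataclass(frozen=True)
class AttributeTestReport:
    """Per-attribute paired test results for a two-textbook contrast."""

    textbook_a: str
    textbook_b: str
    table: pd.DataFrame  # index attributes; statistic, p, p_adj, star, direction
    alpha: float = 0.01
    paired: bool = True


def wilcoxon_attribute_tests(
    X: pd.DataFrame,
    textbooks,
    diseases,
    textbook_a: str,
    textbook_b: str,
    *,
    alpha: float = 0.01,
    paired: bool = True,
) -> AttributeTestReport:
    """Two-sided signed-rank tests of attribute enrichment between two styles.

    Documents of the two textbooks are paired by disease (A minus B); the
    exact null distribution is used for small samples without ties,
    otherwise the normal approximation with continuity correction.  Zero
    differences are dropped (standard signed-rank convention).  BH
    correction runs across the four attributes; stars mark adjusted
    p < ``alpha``.  ``paired=False`` switches to an unpaired Mann-Whitney
    test (off-label sensitivity mode).
    """
    tb = np.asarray(textbooks)
    dis = np.asarray(diseases)
    frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X, columns=ATTRIBUTES)

    a_rows = frame[tb == textbook_a].set_axis(dis[tb == textbook_a], axis=0)
    b_rows = frame[tb == textbook_b].set_axis(dis[tb == textbook_b], axis=0)
    if paired:
        missing = sorted(set(a_rows.index) ^ set(b_rows.index))
        if missing:
            raise ValueError(
                f"incomplete disease pairing between {textbook_a} and "
                f"{textbook_b}: {missing}"
            )
        b_rows = b_rows.loc[a_rows.index]

    rows = []
    for attr in frame.columns:
        if paired:
            diff = a_rows[attr].to_numpy() - b_rows[attr].to_numpy()
            nonzero = diff[diff != 0]
            if len(nonzero) == 0:
                stat, p = 0.0, 1.0
            else:
                if len(nonzero) < 5:
                    warnings.warn(
                        f"only {len(nonzero)} non-zero paired differences for "
                        f"{attr}; test has little power",
                        RuntimeWarning,
                    )
                stat, p = wilcoxon(
                    diff, zero_method="wilcox", alternative="two-sided",
                    correction=True, method="auto",
                )
            direction = (
                f"{textbook_a}>{textbook_b}"
                if diff.sum() > 0
                else f"{textbook_b}>{textbook_a}"
            )
        else:
            stat, p = mannwhitneyu(
                a_rows[attr], b_rows[attr], alternative="two-sided"
            )
            direction = (
                f"{textbook_a}>{textbook_b}"
                if a_rows[attr].mean() > b_rows[attr].mean()
                else f"{textbook_b}>{textbook_a}"
            )
        rows.append({"attribute": attr, "statistic": float(stat), "p": float(p),
                     "direction": direction})

    table = pd.DataFrame(rows).set_index("attribute")
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["star"] = np.where(table["p_adj"] < alpha, "**", "")
    return AttributeTestReport(textbook_a, textbook_b, table, alpha, paired)
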