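"""Permutation test: statistic, empirical null, p conventions, BH."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apstyle import (
    bh_adjust,
    pairwise_distances,
    permutation_test,
    run_similarity_suite,
    same_label_mean_distance,
    suite_to_frame,
)


def brute_pairwise(X):
    n = len(X)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.sqrt(((X[i] - X[j]) ** 2).sum())
    return out


def brute_same_label_mean(D, labels):
    vals = [
        D[i, j]
        for i, j in itertools.combinations(range(len(labels)), 2)
        if labels[i] == labels[j]
    ]
    return float(np.mean(vals))


def exhaustive_p(D, labels):
    """Exact left-tail p over all permutations of the label vector."""
    obs = brute_same_label_mean(D, labels)
    stats = [
        brute_same_label_mean(D, [labels[k] for k in perm])
        for perm in itertools.permutations(range(len(labels)))
    ]
    return float(np.mean([s <= obs + 1e-12 for s in stats]))


class TestDistances:
    def test_identical_rows_distance_zero(self):
        D = pairwise_distances(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert D.iat[0, 1] == 0.0

    def test_unit_axes(self):
        D = pairwise_distances(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert D.iat[0, 1] == pytest.approx(np.sqrt(2))

    def test_matches_loop_oracle(self, rng):
        X = rng.normal(size=(5, 3))
        assert np.allclose(pairwise_distances(X), brute_pairwise(X))

    def test_metric_axioms(self, rng):
        X = rng.normal(size=(6, 4))
        D = pairwise_distances(X).to_numpy()
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0) and (D >= 0).all()
        for i, j, k in itertools.permutations(range(6), 3):
            assert D[i, k] <= D[i, j] + D[j, k] + 1e-12

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            pairwise_distances(np.array([[0.0, np.nan], [1.0, 2.0]]))


class TestSameLabelMean:
    def test_single_pair(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = 0.5
        D[0, 2] = D[2, 0] = 9.0
        D[1, 2] = D[2, 1] = 9.0
        assert same_label_mean_distance(D, ["a", "a", "b"]) == 0.5

    def test_identical_documents_zero(self):
        D = np.zeros((4, 4))
        assert same_label_mean_distance(D, ["a", "a", "b", "b"]) == 0.0

    def test_aabbcc_matches_enumeration(self, rng):
        X = rng.normal(size=(6, 3))
        D = brute_pairwise(X)
        labels = ["A", "A", "B", "B", "C", "C"]
        assert same_label_mean_distance(D, labels) == pytest.approx(
            brute_same_label_mean(D, labels)
        )

    def test_no_shared_label_is_error(self):
        with pytest.raises(ValueError):
            same_label_mean_distance(np.zeros((3, 3)), ["a", "b", "c"])


class TestPermutationTest:
    def test_all_zero_distances(self):
        res = permutation_test(np.zeros((4, 4)), ["a", "a", "b", "b"], B=100, seed=0)
        assert res.observed == res.expected == 0.0
        assert res.p_empirical == 1.0

    def test_exhaustive_matches_enumeration_n4(self, rng):
        X = rng.normal(size=(4, 2))
        D = brute_pairwise(X)
        labels = ["A", "A", "B", "B"]
        res = permutation_test(D, labels, B=24, mode="exhaustive")
        assert res.p_empirical == pytest.approx(exhaustive_p(D, labels))

    def test_auto_switches_to_exhaustive_for_small_n(self, rng):
        X = rng.normal(size=(4, 2))
        res = permutation_test(brute_pairwise(X), ["A", "A", "B", "B"], B=1000)
        assert res.exhaustive and res.B == 24

    def test_determinism(self, rng):
        X = rng.normal(size=(9, 3))
        D = brute_pairwise(X)
        labels = list("AAABBBCCC")
        r1 = permutation_test(D, labels, B=500, seed=42, mode="monte_carlo")
        r2 = permutation_test(D, labels, B=500, seed=42, mode="monte_carlo")
        assert r1 == r2

    def test_null_mean_approaches_grand_mean(self, rng):
        X = rng.normal(size=(8, 3))
        D = brute_pairwise(X)
        res = permutation_test(D, list("AABBCCDD"), B=20000, seed=1, mode="monte_carlo")
        grand = D[np.triu_indices(8, 1)].mean()
        assert abs(res.expected - grand) <= 3 * res.null_sd / np.sqrt(res.B)

    def test_monte_carlo_within_3se_of_exhaustive(self, rng):
        for _ in range(5):
            X = rng.normal(size=(7, 2))
            D = brute_pairwise(X)
            labels = ["A", "A", "A", "B", "B", "C", "C"]
            exact = permutation_test(D, labels, mode="exhaustive").p_empirical
            mc = permutation_test(
                D, labels, B=4000, seed=int(rng.integers(2**31)), mode="monte_carlo"
            ).p_empirical
            se = np.sqrt(exact * (1 - exact) / 4000)
            assert abs(mc - exact) <= max(3 * se, 2 / 4000)

    def test_constant_labels_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(np.zeros((3, 3)), ["a", "a", "a"], B=10)

    def test_zero_budget_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(np.zeros((4, 4)), ["a", "a", "b", "b"], B=0)

    def test_display_convention_for_zero_count(self):
        # observed far below any achievable null: p displays as < 1/B
        from dataclasses import replace

        res = permutation_test(np.zeros((4, 4)), ["a", "a", "b", "b"], B=100, seed=0)
        shown = replace(res, p_empirical=0.0, B=10**5)
        assert shown.p_display == "<1e-05"
        assert replace(res, p_empirical=0.25).p_display == "0.25"

    def test_add_one_convention(self, rng):
        X = rng.normal(size=(9, 3))
        D = brute_pairwise(X)
        labels = list("AAABBBCCC")
        plain = permutation_test(D, labels, B=200, seed=0, mode="monte_carlo")
        conservative = permutation_test(
            D, labels, B=200, seed=0, mode="monte_carlo", add_one=True
        )
        k = round(plain.p_empirical * 200)
        assert conservative.p_empirical == pytest.approx((k + 1) / 201)


class TestBHAdjust:
    def test_hand_worked_stepup(self):
        assert np.allclose(
            bh_adjust([0.01, 0.02, 0.04, 0.05]), [0.04, 0.04, 0.05, 0.05]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_ties_unchanged(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_stepup_oracle(self, ps):
        def oracle(p):
            m = len(p)
            order = np.argsort(p, kind="stable")
            adj = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * m / rank)
                adj[i] = prev
            return adj

        assert np.allclose(bh_adjust(ps), oracle(np.asarray(ps)))


class TestSimilaritySuite:
    def test_three_textbook_suite_has_eight_rows(self, null_corpus):
        suite = run_similarity_suite(null_corpus, B=200, seed=0)
        assert len(suite) == 8
        frame = suite_to_frame(suite)
        assert frame["grouping"].tolist() == ["same textbook", "same disease"] * 4
        # first subset is all three textbooks, then the three pairs
        assert frame["subset"].iloc[0].count("+") == 2
        assert all(s.count("+") == 1 for s in frame["subset"].iloc[2:])
        assert frame["p_adjusted"].notna().all()

    def test_two_textbook_suite_has_four_rows(self, null_corpus):
        corpus = null_corpus.subset(null_corpus.textbooks[:2])
        assert len(run_similarity_suite(corpus, B=100, seed=0)) == 4

    def test_adjusted_p_is_bh_of_raw(self, null_corpus):
        suite = run_similarity_suite(null_corpus, B=300, seed=5)
        raw = [r.p_empirical for r in suite]
        assert np.allclose([r.p_adjusted for r in suite], bh_adjust(raw))

    def test_suite_deterministic(self, null_corpus):
        a = run_similarity_suite(null_corpus, B=200, seed=9)
        b = run_similarity_suite(null_corpus, B=200, seed=9)
        assert a == b
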