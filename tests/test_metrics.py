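import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import auc_pair_counting, ef_top_k, mannwhitney_exact_p
from screenaudit.errors import DomainError, IntegrityError, UndefinedMetricError
from screenaudit.metrics import (MetricResult, bootstrap_interval,
                                 compare_distributions, enrichment_factor,
                                 max_enrichment_factor, normalized_ef, roc_auc,
                                 significant_win_count, summarize_benchmark)


def binary_instance(draw_labels=True, max_n=20):
    """Hypothesis strategy: (labels, scores) with both classes present."""
    return st.integers(2, max_n).flatmap(lambda n: st.tuples(
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda ls: 0 < sum(ls) < len(ls)),
        st.lists(st.floats(-100, 100, allow_nan=False), min_size=n, max_size=n),
    ))


class TestRocAuc:
    def test_interleaved_ranking(self):
        # 4 active-inactive pairs; active(4) beats both inactives, active(2)
        # beats only score 1 -> 3/4
        assert roc_auc([1, 0, 1, 0], [4, 3, 2, 1]) == pytest.approx(0.75)

    def test_perfect_ranking_is_one(self):
        labels = [1] * 5 + [0] * 20
        scores = list(range(25, 0, -1))
        assert roc_auc(labels, scores) == pytest.approx(1.0)

    def test_all_tied_scores_give_half(self):
        assert roc_auc([1, 0, 1, 0, 0], [3.3] * 5) == pytest.approx(0.5)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    @given(binary_instance())
    @settings(max_examples=150, deadline=None)
    def test_matches_pair_counting_oracle(self, inst):
        labels, scores = inst
        assert roc_auc(labels, scores) == pytest.approx(
            auc_pair_counting(labels, scores), abs=1e-12)

    @given(binary_instance())
    @settings(max_examples=80, deadline=None)
    def test_score_negation_complements(self, inst):
        labels, scores = inst
        total = roc_auc(labels, scores) + roc_auc(labels, [-s for s in scores])
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        """Independent library route on tie-free data."""
        from sklearn.metrics import roc_auc_score

        labels = rng.integers(0, 2, 300)
        labels[:2] = [0, 1]
        scores = rng.normal(size=300)
        assert roc_auc(labels, scores) == pytest.approx(roc_auc_score(labels, scores))


class TestEnrichmentFactor:
    def test_half_of_top_percent_active(self, rng):
        # 1000 compounds, 10 actives, 5 of them in the top 10 -> EF1% = 50
        labels = np.zeros(1000, dtype=int)
        labels[:10] = 1
        scores = np.linspace(1000, 1, 1000)  # descending with position
        labels_arranged = np.zeros(1000, dtype=int)
        labels_arranged[[0, 2, 4, 6, 8]] = 1          # 5 actives inside top 10
        labels_arranged[[500, 600, 700, 800, 900]] = 1  # 5 far below
        assert enrichment_factor(labels_arranged, scores, 0.01) == pytest.approx(50.0)

    def test_no_actives_in_top_k_is_zero(self):
        labels = [0] * 99 + [1]
        scores = list(range(100, 0, -1))
        assert enrichment_factor(labels, scores, 0.01) == 0.0

    @given(binary_instance())
    @settings(max_examples=80, deadline=None)
    def test_alpha_one_is_identically_one(self, inst):
        labels, scores = inst
        assert enrichment_factor(labels, scores, 1.0) == pytest.approx(1.0)

    @given(binary_instance(), st.floats(0.05, 1.0))
    @settings(max_examples=150, deadline=None)
    def test_matches_top_k_oracle(self, inst, alpha):
        labels, scores = inst
        assert enrichment_factor(labels, scores, alpha) == pytest.approx(
            ef_top_k(labels, scores, alpha), abs=1e-12)

    def test_moving_active_above_boundary_never_decreases_ef(self, rng):
        n, alpha = 200, 0.05
        scores = np.sort(rng.normal(size=n))[::-1].copy()
        labels = np.zeros(n, dtype=int)
        labels[50] = 1   # below the k=10 boundary
        labels[150] = 1
        before = enrichment_factor(labels, scores, alpha)
        labels2 = np.zeros(n, dtype=int)
        labels2[5] = 1   # moved above the boundary
        labels2[150] = 1
        assert enrichment_factor(labels2, scores, alpha) >= before

    def test_boundary_ties_broken_by_compound_id(self):
        labels = [1, 0, 0, 0]
        scores = [0.5, 0.5, 0.1, 0.1]
        # k=1; tie between ids "a"(active) and "b": "a" wins the slot
        assert enrichment_factor(labels, scores, 0.25, ids=["a", "b", "c", "d"]) > 0
        assert enrichment_factor(labels, scores, 0.25, ids=["z", "b", "c", "d"]) == 0


class TestMaxAndNormalizedEf:
    @pytest.mark.parametrize("n_act,n_total,alpha,expected", [
        (10, 1000, 0.01, 100.0),
        (50, 1000, 0.01, 20.0),
        (7, 7, 0.01, 1.0),     # every compound active
    ])
    def test_max_ef(self, n_act, n_total, alpha, expected):
        assert max_enrichment_factor(n_act, n_total, alpha) == pytest.approx(expected)

    def test_zero_actives_undefined(self):
        with pytest.raises(UndefinedMetricError):
            max_enrichment_factor(0, 100, 0.01)

    def test_all_actives_on_top_gives_one(self):
        labels = np.zeros(1000, dtype=int)
        labels[:10] = 1
        scores = np.linspace(1000, 1, 1000)
        assert normalized_ef(labels, scores, 0.01) == pytest.approx(1.0)

    def test_no_actives_on_top_gives_zero(self):
        labels = np.zeros(1000, dtype=int)
        labels[-10:] = 1
        scores = np.linspace(1000, 1, 1000)
        assert normalized_ef(labels, scores, 0.01) == 0.0

    def test_nef_is_ef_over_max_ef(self):
        # EF 50 (worked example above) with max EF 100 -> NEF 0.5
        scores = np.linspace(1000, 1, 1000)
        labels = np.zeros(1000, dtype=int)
        labels[[0, 2, 4, 6, 8]] = 1
        labels[[500, 600, 700, 800, 900]] = 1
        assert normalized_ef(labels, scores, 0.01) == pytest.approx(0.5)

    @given(binary_instance(), st.floats(0.05, 1.0))
    @settings(max_examples=80, deadline=None)
    def test_bounds(self, inst, alpha):
        labels, scores = inst
        ef = enrichment_factor(labels, scores, alpha)
        max_ef = max_enrichment_factor(sum(labels), len(labels), alpha)
        nef = normalized_ef(labels, scores, alpha)
        assert 0 <= ef <= max_ef + 1e-12
        assert -1e-12 <= nef <= 1 + 1e-12


class TestMonotoneInvariance:
    @given(st.integers(2, 20).flatmap(lambda n: st.tuples(
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda ls: 0 < sum(ls) < len(ls)),
        # coarse grid keeps the transform strictly increasing in floats
        st.lists(st.integers(-300, 300).map(lambda v: v / 7.0),
                 min_size=n, max_size=n))))
    @settings(max_examples=60, deadline=None)
    def test_auc_and_ef_invariant_under_increasing_transform(self, inst):
        labels, scores = inst
        transformed = [np.arctan(s / 30.0) * 7 + 2 for s in scores]
        assert roc_auc(labels, scores) == pytest.approx(
            roc_auc(labels, transformed), abs=1e-9)
        assert enrichment_factor(labels, scores, 0.2) == pytest.approx(
            enrichment_factor(labels, transformed, 0.2), abs=1e-9)


class TestBootstrapInterval:
    def test_degenerate_scores_zero_width(self):
        labels = [1] * 5 + [0] * 20
        scores = [1.0] * 5 + [0.0] * 20
        lo, hi = bootstrap_interval(labels, scores, "auc", n_boot=200, seed=0)
        assert lo == hi == pytest.approx(1.0)

    def test_point_estimate_inside_interval(self, rng):
        labels = np.r_[np.ones(25, int), np.zeros(75, int)]
        scores = rng.normal(size=100) + labels
        lo, hi = bootstrap_interval(labels, scores, "auc", n_boot=10_000, seed=1)
        assert lo <= roc_auc(labels, scores) <= hi

    def test_reproducible_under_seed(self, rng):
        labels = np.r_[np.ones(10, int), np.zeros(40, int)]
        scores = rng.normal(size=50)
        a = bootstrap_interval(labels, scores, "nef", alpha=0.1, n_boot=300, seed=7)
        b = bootstrap_interval(labels, scores, "nef", alpha=0.1, n_boot=300, seed=7)
        assert a == b

    def test_invalid_level_rejected(self):
        with pytest.raises(DomainError):
            bootstrap_interval([1, 0], [1.0, 0.0], n_boot=100, level=1.5)


class TestCompareDistributions:
    def test_fully_separated_small_samples(self):
        # exact: only 2 of C(6,3)=20 orderings are as extreme -> p = 0.1
        assert compare_distributions([1, 2, 3], [4, 5, 6]).p_value == pytest.approx(0.1)

    def test_identical_vectors_give_p_one(self):
        assert compare_distributions([1, 2, 3], [1, 2, 3]).p_value == pytest.approx(1.0)

    def test_all_tied_gives_p_one(self):
        assert compare_distributions([5, 5], [5, 5, 5]).p_value == pytest.approx(1.0)

    def test_ties_handled_with_midranks(self):
        res = compare_distributions([1, 2, 2, 3], [2, 3, 3, 4])
        assert 0 < res.p_value <= 1.0

    def test_empty_vector_rejected(self):
        with pytest.raises(DomainError):
            compare_distributions([], [1.0])

    @pytest.mark.parametrize("n_a,n_b", [(2, 3), (4, 4), (5, 2), (6, 6)])
    def test_matches_enumeration_oracle(self, n_a, n_b, rng):
        for _ in range(5):
            a = rng.permutation(np.arange(n_a + n_b, dtype=float))[:n_a]
            b = np.setdiff1d(np.arange(n_a + n_b, dtype=float), a)
            assert compare_distributions(a, b).p_value == pytest.approx(
                mannwhitney_exact_p(a, b), abs=1e-9)

    def test_exact_close_to_normal_approximation_at_8v8(self, rng):
        from scipy.stats import mannwhitneyu
        for _ in range(10):
            a = rng.normal(size=8)
            b = rng.normal(0.5, 1, size=8)
            exact = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            approx = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
            assert abs(exact - approx) < 0.02


class TestSummarizeBenchmark:
    @staticmethod
    def _results(values_by_method):
        out = []
        for method, values in values_by_method.items():
            for i, v in enumerate(values):
                out.append(MetricResult(f"T{i}", method, "nef", v, alpha=0.01))
        return out

    def test_median_over_targets(self):
        df = summarize_benchmark(self._results({"m": [0.1, 0.2, 0.3]}))
        assert df.loc[0, "median"] == pytest.approx(0.2)

    def test_single_target_median_is_value(self):
        df = summarize_benchmark(self._results({"m": [0.42]}))
        assert df.loc[0, "median"] == pytest.approx(0.42)

    def test_best_flags_match_independent_argmax(self, rng):
        # 7 targets per method keeps the comparison on the exact-test path,
        # matching the enumeration oracle
        values = {m: rng.random(7).tolist() for m in ["m1", "m2", "m3"]}
        df = summarize_benchmark(self._results(values))
        best_expected = max(sorted(values), key=lambda m: float(np.median(values[m])))
        assert df.loc[df["is_best"], "method"].tolist() == [best_expected]
        # p-vs-best recomputed through an independent route
        others = [m for m in values if m != best_expected]
        for m in others:
            p_direct = mannwhitney_exact_p(values[m], values[best_expected])
            got = float(df.loc[df["method"] == m, "p_vs_best"].iloc[0])
            assert got == pytest.approx(p_direct, abs=1e-9)


class TestSignificantWinCount:
    def test_identical_methods_all_undecided(self, rng):
        per_target = {}
        for t in range(4):
            labels = np.r_[np.ones(10, int), np.zeros(40, int)]
            s = rng.normal(size=50)
            per_target[f"T{t}"] = (labels, s, s)
        wins = significant_win_count(per_target, metric="auc", n_boot=200, seed=0)
        assert wins == (0, 0, 4)

    def test_counts_conserve_target_number(self, rng):
        per_target = {}
        for t in range(5):
            labels = np.r_[np.ones(15, int), np.zeros(60, int)]
            per_target[f"T{t}"] = (labels, rng.normal(size=75) + labels,
                                   rng.normal(size=75))
        wa, wb, und = significant_win_count(per_target, metric="auc",
                                            n_boot=200, seed=0)
        assert wa + wb + und == 5

    def test_dominant_method_wins_every_target(self, rng):
        """A's separation far exceeds B's on every target; at n = 2000 the
        paired bootstrap must call all 10 targets for A."""
        per_target = {}
        for t in range(10):
            labels = np.r_[np.ones(100, int), np.zeros(1900, int)]
            sa = rng.normal(size=2000) + 1.5 * labels
            sb = rng.normal(size=2000) + 0.2 * labels
            per_target[f"T{t}"] = (labels, sa, sb)
        wins = significant_win_count(per_target, metric="auc", n_boot=200, seed=3)
        assert wins == (10, 0, 0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(IntegrityError):
            significant_win_count({"T0": ([1, 0], [1.0, 0.0], [1.0])}, n_boot=100)
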