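import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sfindex as s
from sfindex.evaluation import ROCResult, hm_auc_correlation


def brute_force_auc(pos, neg):
    """Exhaustive pairwise concordance: P(pos > neg) + 0.5 P(tie)."""
    wins = ties = 0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def labels_for(n_pos, n_neg):
    return ["glaucoma"] * n_pos + ["suspect"] * n_neg


class TestROC:
    def test_perfect_separation(self):
        scores = [5, 6, 7, 1, 2, 3]
        r = s.roc(scores, labels_for(3, 3))
        assert r.auc == 1.0
        assert r.n_pos == 3 and r.n_neg == 3

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 2**31 - 1), ties=st.booleans())
    def test_mann_whitney_oracle(self, seed, ties):
        rng = np.random.default_rng(seed)
        n_pos = int(rng.integers(2, 50))
        n_neg = int(rng.integers(2, 50))
        if ties:
            pos = rng.integers(0, 6, n_pos).astype(float)
            neg = rng.integers(0, 6, n_neg).astype(float)
        else:
            pos = rng.normal(1, 1, n_pos)
            neg = rng.normal(0, 1, n_neg)
        r = s.roc(np.concatenate([pos, neg]), labels_for(n_pos, n_neg))
        assert r.auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    def test_curve_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=80)
        scores[:40] += 1
        r = s.roc(scores, labels_for(40, 40))
        assert np.all(np.diff(r.thresholds) > 0)
        assert np.all(np.diff(r.sensitivity) <= 0)
        assert np.all(np.diff(r.specificity) >= 0)

    def test_auc_equals_trapezoid_of_stored_curve(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=60)
        scores[:30] += 0.8
        r = s.roc(scores, labels_for(30, 30))
        fpr = np.concatenate([[0.0], 1.0 - r.specificity[::-1], [1.0]])
        tpr = np.concatenate([[0.0], r.sensitivity[::-1], [1.0]])
        assert r.auc == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)

    def test_one_class_input_rejected(self):
        with pytest.raises(ValueError):
            s.roc([1.0, 2.0], ["glaucoma", "glaucoma"])


class TestAucSE:
    def test_plug_in_arithmetic_at_half(self):
        r = ROCResult(
            thresholds=np.array([0.5]), sensitivity=np.array([0.5]),
            specificity=np.array([0.5]), auc=0.5, auc_se=0.0,
            n_pos=100, n_neg=100,
        )
        expected = math.sqrt(
            (0.25 + 99 * (1 / 3 - 0.25) + 99 * (1 / 3 - 0.25)) / 10000
        )
        assert s.auc_se(r) == pytest.approx(expected, abs=1e-15)

    def test_decreases_with_n_and_vanishes_at_one(self):
        def se(auc, n):
            r = ROCResult(
                thresholds=np.array([0.0]), sensitivity=np.array([1.0]),
                specificity=np.array([1.0]), auc=auc, auc_se=0.0,
                n_pos=n, n_neg=n,
            )
            return s.auc_se(r)

        assert se(0.8, 200) < se(0.8, 50)
        assert se(0.9999, 100) < se(0.8, 100)
        with pytest.warns(UserWarning):
            assert se(1.0, 100) == 0.0


class TestCompareAuc:
    def _roc_pair(self, shift_b=0.0, seed=0, n=60):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=2 * n)
        base[:n] += 1.0
        a = s.roc(base, labels_for(n, n))
        b = s.roc(base + shift_b + rng.normal(0, 0.3, 2 * n), labels_for(n, n))
        return a, b

    def test_identical_scores_give_zero_z(self):
        a, _ = self._roc_pair()
        z, p = s.compare_auc(a, a)
        assert z == 0.0 and p == 1.0

    def test_antisymmetric_in_argument_order(self):
        a, b = self._roc_pair(seed=5)
        z_ab, _ = s.compare_auc(a, b)
        z_ba, _ = s.compare_auc(b, a)
        assert z_ab == pytest.approx(-z_ba, abs=1e-12)

    def test_unpaired_reduces_to_plain_z_test(self):
        a, b = self._roc_pair(seed=6)
        z, p = s.compare_auc(a, b, paired=False)
        expected = (a.auc - b.auc) / math.sqrt(a.auc_se**2 + b.auc_se**2)
        assert z == pytest.approx(expected, abs=1e-12)

    def test_paired_correlation_tightens_the_test(self):
        a, b = self._roc_pair(seed=7)
        z_paired, _ = s.compare_auc(a, b, paired=True)
        z_unpaired, _ = s.compare_auc(a, b, paired=False)
        assert abs(z_paired) >= abs(z_unpaired) - 1e-12

    def test_correlation_table_behaviour(self):
        # vanishing rank correlation -> vanishing AUC correlation
        assert hm_auc_correlation(0.0, 0.8) == pytest.approx(0.0, abs=0.02)
        # attenuation at high AUC
        assert hm_auc_correlation(0.6, 0.975) < hm_auc_correlation(0.6, 0.7)
        # monotone-ish growth with the score correlation
        assert hm_auc_correlation(0.8, 0.8) > hm_auc_correlation(0.2, 0.8)


class TestBinaryPerformance:
    def test_all_correct(self):
        labels = labels_for(5, 5)
        pred = [l == "glaucoma" for l in labels]
        perf = s.binary_performance(pred, labels)
        assert perf.sensitivity == 1.0 and perf.specificity == 1.0
        assert perf.sensitivity_ci[0] < 1.0 <= perf.sensitivity_ci[1]

    def test_counting_arithmetic(self):
        labels = labels_for(100, 50)
        pred = [True] * 58 + [False] * 42 + [False] * 50
        perf = s.binary_performance(pred, labels)
        assert perf.sensitivity == pytest.approx(0.58)
        assert perf.specificity == 1.0
        assert (perf.tp, perf.fn, perf.tn, perf.fp) == (58, 42, 50, 0)

    def test_cis_contain_point_estimates(self):
        rng = np.random.default_rng(9)
        labels = labels_for(40, 60)
        pred = rng.random(100) < 0.5
        perf = s.binary_performance(pred, labels)
        assert perf.sensitivity_ci[0] <= perf.sensitivity <= perf.sensitivity_ci[1]
        assert perf.specificity_ci[0] <= perf.specificity <= perf.specificity_ci[1]

    def test_or_combination_never_loses_sensitivity(self):
        rng = np.random.default_rng(12)
        labels = labels_for(80, 80)
        t1 = rng.random(160) < 0.4
        t2 = rng.random(160) < 0.4
        both = t1 | t2
        sens = lambda p: s.binary_performance(p, labels).sensitivity
        assert sens(both) >= max(sens(t1), sens(t2))


class TestOptimalPoint:
    def test_perfect_classifier_distance_zero(self):
        r = s.roc([10, 11, 12, 1, 2, 3], labels_for(3, 3))
        thr = s.optimal_point(r)
        i = np.where(r.thresholds == thr)[0][0]
        assert r.sensitivity[i] == 1.0 and r.specificity[i] == 1.0

    def test_brute_force_scan_agreement(self):
        rng = np.random.default_rng(21)
        scores = rng.normal(size=100)
        scores[:50] += 1.2
        r = s.roc(scores, labels_for(50, 50))
        d2 = (1 - r.sensitivity) ** 2 + (1 - r.specificity) ** 2
        best = np.inf
        best_thr = None
        for t, d in zip(r.thresholds, d2):
            if d < best:  # strict: keeps the lowest threshold on ties
                best, best_thr = d, t
        assert s.optimal_point(r) == best_thr

    def test_tie_goes_to_lower_threshold(self):
        # interleaved scores: thresholds 2 and 4 both sit at distance 0.5
        # from (1, 1) — (sens, spec) = (1, 0.5) and (0.5, 1) respectively
        scores = [2, 4, 1, 3]
        labels = ["glaucoma", "glaucoma", "suspect", "suspect"]
        r = s.roc(scores, labels)
        d2 = (1 - r.sensitivity) ** 2 + (1 - r.specificity) ** 2
        assert np.isclose(d2.min(), d2).sum() >= 2
        assert s.optimal_point(r) == 2.0


class TestConcordanceTable:
    def test_counts_conserve_n_and_match_brute_force(self):
        rng = np.random.default_rng(30)
        n = 200
        outcomes = {t: rng.random(n) < 0.5 for t in ("sfi", "ght", "mfc")}
        table = s.concordance_table(outcomes)
        assert sum(table.values()) == n
        for pattern, count in table.items():
            manual = sum(
                1
                for i in range(n)
                if tuple(bool(outcomes[t][i]) for t in ("sfi", "ght", "mfc"))
                == pattern
            )
            assert manual == count

    def test_degenerate_all_positive(self):
        table = s.concordance_table({"a": [True] * 7, "b": [True] * 7})
        assert table == {(True, True): 7}

    def test_md_stratified_subset(self):
        md = np.array([-1.0, -6.0, -12.0, -2.0])
        outcomes = {"a": [True, False, True, True]}
        mild = s.concordance_table(outcomes, mask=md > -5)
        assert sum(mild.values()) == 2

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            s.concordance_table({"a": [True], "b": [True, False]})
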