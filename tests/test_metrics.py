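import math
from itertools import product

import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from pathopred.errors import ConfigurationError, DegenerateLabelsError
from pathopred.metrics import (
    balanced_precision,
    compare,
    evaluate_binary,
    pr_curve,
    precision_from_balanced,
)

from _oracles import brute_force_auprc, brute_force_auroc


class TestBalancedPrecision:
    def test_balanced_prior_is_identity(self):
        for p in np.linspace(0.05, 0.95, 19):
            assert math.isclose(balanced_precision(p, 0.5), p, abs_tol=1e-12)

    def test_precision_equal_to_prior_gives_half(self):
        for prior in np.linspace(0.05, 0.95, 19):
            assert math.isclose(balanced_precision(prior, prior), 0.5, abs_tol=1e-12)

    def test_worked_fraction(self):
        assert math.isclose(balanced_precision(0.9, 0.1), 81 / 82, abs_tol=1e-12)

    def test_round_trip_inverse(self, rng):
        for _ in range(50):
            p, prior = rng.uniform(0.01, 0.99, 2)
            bp = balanced_precision(p, prior)
            assert math.isclose(precision_from_balanced(bp, prior), p, abs_tol=1e-12)

    @pytest.mark.parametrize("prior", [0.0, 1.0])
    def test_degenerate_prior_rejected(self, prior):
        with pytest.raises(DegenerateLabelsError):
            balanced_precision(0.5, prior)


class TestEvaluateBinary:
    def test_perfect_classifier_all_ones(self):
        scores = [5, 4, 3, 2, 1, 0]
        labels = [1, 1, 0, 0, 0, 0]
        b = evaluate_binary(scores, labels)
        assert b.auprc == b.aubprc_pointwise == b.aubprc_eq7 == b.r90bp == b.auroc == 1.0

    def test_worked_example_101(self):
        b = evaluate_binary([3, 2, 1], [1, 0, 1])
        assert math.isclose(b.auprc, 5 / 6, abs_tol=1e-12)
        assert math.isclose(b.aubprc_eq7, 5 / 7, abs_tol=1e-12)
        # pointwise transform differs from the closed form on stepped curves
        assert math.isclose(b.aubprc_pointwise, 0.75, abs_tol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            evaluate_binary([1, 2, 3], [1, 1, 1])

    def test_ties_grouped_into_one_curve_point(self):
        curve = pr_curve(np.array([1.0, 1.0, 0.5]), np.array([1, 0, 1]))
        assert len(curve) == 2

    def test_auprc_matches_brute_force_on_all_small_patterns(self, rng):
        for n in (2, 3, 4, 5):
            for pattern in product([0, 1], repeat=n):
                if sum(pattern) in (0, n):
                    continue
                for _ in range(3):
                    scores = rng.normal(size=n)
                    b = evaluate_binary(scores, pattern)
                    assert math.isclose(
                        b.auprc, brute_force_auprc(scores, pattern), abs_tol=1e-12
                    )
                    assert math.isclose(
                        b.auprc,
                        average_precision_score(pattern, scores),
                        abs_tol=1e-12,
                    )

    def test_auroc_matches_pairwise_count_and_sklearn(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 12))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.normal(size=n), 1)  # provoke ties
            b = evaluate_binary(scores, labels)
            assert math.isclose(b.auroc, brute_force_auroc(scores, labels), abs_tol=1e-12)
            assert math.isclose(b.auroc, roc_auc_score(labels, scores), abs_tol=1e-12)

    @pytest.mark.parametrize("blocks", [[(1, 1), (2, 2)], [(2, 1), (4, 2), (2, 1)]])
    def test_constant_precision_makes_pointwise_equal_eq7(self, blocks):
        # tied-score blocks with identical class ratios keep precision constant
        scores, labels = [], []
        for i, (npos, nneg) in enumerate(blocks):
            scores += [float(len(blocks) - i)] * (npos + nneg)
            labels += [1] * npos + [0] * nneg
        b = evaluate_binary(scores, labels)
        assert math.isclose(b.aubprc_pointwise, b.aubprc_eq7, abs_tol=1e-12)

    def test_duplicating_negatives_changes_prior_not_balanced_precision(self, rng):
        scores = rng.normal(size=30)
        labels = np.array([1] * 10 + [0] * 20)
        base = pr_curve(scores, labels)
        dup_scores = np.concatenate([scores, scores[labels == 0], scores[labels == 0]])
        dup_labels = np.concatenate([labels, np.zeros(40, dtype=int)])
        dup = pr_curve(dup_scores, dup_labels)
        merged = base.merge(dup, on="threshold", suffixes=("_a", "_b"))
        assert len(merged) == len(base)
        np.testing.assert_allclose(
            merged["balanced_precision_a"], merged["balanced_precision_b"], atol=1e-12
        )

    def test_r90bp_takes_last_downward_crossing(self):
        # prior 0.5 so balanced precision equals precision; BP curve points:
        # (R=1/3, 1), (2/3, 1), (2/3, 2/3), (1, 3/4), (1, 3/5), (1, 1/2) —
        # the only crossing from above 0.9 happens at recall 2/3
        b = evaluate_binary([6, 5, 4, 3, 2, 1], [1, 1, 0, 1, 0, 0], bp_target=0.9)
        assert math.isclose(b.r90bp, 2 / 3, abs_tol=1e-12)

    def test_r90bp_one_when_perfect_up_to_full_recall(self):
        b = evaluate_binary([6, 5, 4, 3, 2, 1], [1, 1, 1, 0, 0, 0], bp_target=0.9)
        assert b.r90bp == 1.0

    def test_r90bp_zero_when_never_reached(self):
        b = evaluate_binary([4, 3, 2, 1], [0, 1, 0, 1], bp_target=0.9)
        assert b.r90bp == 0.0

    def test_r90bp_one_when_curve_ends_above_target(self):
        b = evaluate_binary([2, 1], [1, 0], bp_target=0.5)
        assert b.r90bp == 1.0


class TestCompare:
    def test_identical_scores_degenerate_p_one(self, rng):
        scores = rng.normal(size=40)
        labels = np.array([1] * 20 + [0] * 20)
        res = compare(scores, scores, labels, method="bootstrap_z", n=50, seed=0)
        assert res.degenerate and res.p_value == 1.0

    def test_perfect_vs_antiperfect_significant(self, rng):
        labels = np.array([1] * 100 + [0] * 100)
        rng.shuffle(labels)
        a = labels + rng.normal(0, 0.1, 200)  # near-perfect
        b = -a  # anti-perfect
        res = compare(a, b, labels, metric="aubprc", method="bootstrap_z",
                      n=200, seed=1)
        assert res.p_value < 0.05

    def test_paired_t_matches_scipy_one_sided(self, rng):
        from scipy import stats

        a = rng.normal(0.9, 0.02, 10)
        b = a - rng.uniform(0.0, 0.03, 10)
        res = compare(a, b, method="paired_t")
        ref = stats.ttest_rel(a, b, alternative="greater")
        assert math.isclose(res.statistic, ref.statistic)
        assert math.isclose(res.p_value, ref.pvalue)
        assert res.n_resamples_or_df == 9

    def test_paired_t_constant_positive_difference_degenerate_zero(self):
        a = np.full(10, 0.9)
        b = np.full(10, 0.85)
        res = compare(a, b, method="paired_t")
        assert res.degenerate and res.p_value == 0.0

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigurationError):
            compare([1], [2], [1], method="wilcoxon")
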