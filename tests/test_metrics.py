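"""Metric suite: confusion tallies, PRF, micro-averages, ROC-AUC, Scott's Pi."""
import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from cuckoofuse import (
    accuracy,
    agreement_matrix,
    confusion_counts,
    evaluate,
    micro_average,
    per_class_prf,
    roc_auc_micro,
    scotts_pi,
)
from cuckoofuse.errors import UndefinedMetricError, ValidationError


def auc_pairwise_oracle(truth, probs):
    """Exhaustive positive-vs-negative comparison on the flattened OVR
    expansion; ties count 1/2. Independent of the implementation under test."""
    truth = np.asarray(truth)
    probs = np.asarray(probs, dtype=float)
    n, K = probs.shape
    y = np.zeros((n, K))
    y[np.arange(n), truth] = 1
    y, s = y.ravel(), probs.ravel()
    pos, neg = s[y == 1], s[y == 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (len(pos) * len(neg))


class TestConfusionCounts:
    def test_perfect_prediction_has_no_errors(self):
        truth = np.array([0, 1, 2, 3, 0, 1, 2, 3])
        c = confusion_counts(truth, truth, 4)
        assert np.all(c.fp == 0) and np.all(c.fn == 0)
        assert c.tp.sum() == 8

    def test_hand_tally(self):
        c = confusion_counts([0, 1, 2, 3], [0, 1, 2, 0], 4)
        assert (c.tp[0], c.fp[0], c.fn[0], c.tn[0]) == (1, 1, 0, 2)
        assert (c.tp[3], c.fp[3], c.fn[3], c.tn[3]) == (0, 0, 1, 3)

    def test_single_sample(self):
        c = confusion_counts([2], [2], 4)
        assert c.tp[2] == 1
        assert all(c.tn[k] == 1 for k in range(4) if k != 2)

    def test_counts_partition_every_class(self):
        rng = np.random.default_rng(5)
        truth = rng.integers(0, 4, 50)
        pred = rng.integers(0, 4, 50)
        c = confusion_counts(truth, pred, 4)
        assert np.all(c.tp + c.fp + c.fn + c.tn == 50)
        assert c.tp.sum() == np.sum(truth == pred)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion_counts([0, 1], [0], 2)


class TestPRF:
    def test_direct_evaluation(self):
        from cuckoofuse.metrics import ConfusionCounts
        c = ConfusionCounts(tp=np.array([1]), fp=np.array([1]),
                            fn=np.array([0]), tn=np.array([2]))
        (p, _), (r, _), (f, _) = per_class_prf(c)
        assert p[0] == 0.5 and r[0] == 1.0 and f[0] == pytest.approx(2 / 3)

    def test_zero_denominator_flagged_not_raised(self):
        from cuckoofuse.metrics import ConfusionCounts
        c = ConfusionCounts(tp=np.array([0]), fp=np.array([0]),
                            fn=np.array([3]), tn=np.array([1]))
        (p, p_und), _, _ = per_class_prf(c)
        assert p[0] == 0.0 and p_und[0]

    def test_f1_equals_p_when_p_equals_r(self):
        # harmonic-mean identity on real tallies with P == R
        c = confusion_counts([0, 1, 0, 1], [0, 0, 1, 1], 2)
        (p, _), (r, _), (f, _) = per_class_prf(c)
        assert np.allclose(p, r)
        assert np.allclose(f, p)


class TestAccuracyAndMicro:
    def test_hand_count(self):
        assert accuracy([0, 1, 2, 3], [0, 1, 2, 0]) == 0.75

    def test_extremes(self):
        assert accuracy([1, 1], [1, 1]) == 1.0
        assert accuracy([0, 1], [1, 0]) == 0.0

    def test_micro_pools_counts(self):
        c = confusion_counts([0, 1, 2, 3], [0, 1, 2, 0], 4)
        mp, mr, mf = micro_average(c)
        assert mp == mr == mf == 0.75

    def test_micro_equals_accuracy_on_random_single_label_tasks(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            K = int(rng.integers(2, 6))
            n = int(rng.integers(1, 40))
            truth = rng.integers(0, K, n)
            pred = rng.integers(0, K, n)
            mp, mr, mf = micro_average(confusion_counts(truth, pred, K))
            acc = accuracy(truth, pred)
            assert mp == pytest.approx(acc) and mr == pytest.approx(acc)
            assert mf == pytest.approx(acc)


class TestRocAuc:
    def test_one_hot_truth_is_perfect(self):
        truth = [0, 1, 2]
        probs = np.eye(3)
        assert roc_auc_micro(truth, probs) == 1.0

    def test_uniform_scores_are_chance(self):
        probs = np.full((4, 3), 1 / 3)
        assert roc_auc_micro([0, 1, 2, 0], probs) == 0.5

    def test_separable_binary_case(self):
        probs = np.array([[0.9, 0.1], [0.6, 0.4], [0.2, 0.8]])
        assert roc_auc_micro([0, 0, 1], probs) == 1.0

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            K = int(rng.integers(2, 6))
            n = int(rng.integers(2, 200 // K + 1))
            truth = rng.integers(0, K, n)
            # discretized scores force ties so the 1/2 rule is exercised
            probs = np.round(rng.dirichlet(np.ones(K), size=n), 1)
            assert roc_auc_micro(truth, probs) == pytest.approx(
                auc_pairwise_oracle(truth, probs), abs=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc_micro([0], np.array([[1.0, 0.0]]))


class TestScottsPi:
    def test_perfect_agreement(self):
        res = scotts_pi([0, 1, 2, 1], [0, 1, 2, 1], 3)
        assert res.pi == 1.0

    def test_hand_example(self):
        res = scotts_pi([0, 0, 1, 1], [0, 1, 1, 1], 2)
        assert res.po == 0.75
        assert res.pe == pytest.approx(17 / 32)
        assert res.pi == pytest.approx(7 / 15)

    def test_degenerate_marginals_undefined(self):
        res = scotts_pi([0, 0, 0], [0, 0, 0], 3)
        assert res.pi is None and not res.defined

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 4, 30)
        b = rng.integers(0, 4, 30)
        for weighting in ("none", "linear", "quadratic"):
            ra = scotts_pi(a, b, 4, weighting)
            rb = scotts_pi(b, a, 4, weighting)
            assert ra.pi == pytest.approx(rb.pi)

    def test_equals_cohen_kappa_on_equal_marginals(self):
        """With identical marginal distributions the pooled-marginal chance
        term coincides with Cohen's per-rater term, so pi == kappa."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            K = int(rng.integers(2, 5))
            a = rng.integers(0, K, 60)
            b = a.copy()
            rng.shuffle(b)  # permutation => identical marginals
            if np.unique(a).size < 2:
                continue
            res = scotts_pi(a, b, K)
            assert res.pi == pytest.approx(cohen_kappa_score(a, b), abs=1e-10)

    def test_weighted_pi_forgives_adjacent_disagreement(self):
        a = [0, 1, 2, 3, 0, 3]
        b = [1, 0, 3, 2, 0, 3]  # all disagreements are adjacent
        unweighted = scotts_pi(a, b, 4, "none").pi
        linear = scotts_pi(a, b, 4, "linear").pi
        quadratic = scotts_pi(a, b, 4, "quadratic").pi
        assert unweighted < linear < quadratic

    def test_pi_is_one_iff_no_weighted_disagreement(self):
        # quadratic weighting: agreement only exact matches are weight-1,
        # so pi == 1 exactly when the streams coincide
        res = scotts_pi([0, 2, 1], [0, 2, 1], 3, "quadratic")
        assert res.pi == 1.0
        res2 = scotts_pi([0, 2, 1], [0, 2, 2], 3, "quadratic")
        assert res2.pi < 1.0


class TestAgreementMatrixAndReport:
    def test_matrix_matches_cellwise_calls(self):
        rng = np.random.default_rng(13)
        streams = [rng.integers(0, 3, 40) for _ in range(3)]
        mat = agreement_matrix(streams, 3)
        for i in range(3):
            for j in range(3):
                assert mat[i, j] == pytest.approx(
                    scotts_pi(streams[i], streams[j], 3).pi)
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)

    def test_full_report_consistency(self):
        rng = np.random.default_rng(17)
        truth = rng.integers(0, 4, 100)
        probs = rng.dirichlet(np.ones(4), size=100)
        rep = evaluate(truth, probs, ["a", "b", "c", "d"])
        assert rep.micro_precision == rep.micro_recall == rep.micro_f1 == rep.accuracy
        d = rep.to_dict()
        assert set(d["per_class"]) == {"a", "b", "c", "d"}
        assert 0.0 <= d["roc_auc_micro"] <= 1.0
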