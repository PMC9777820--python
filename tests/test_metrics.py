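"""Confusion metrics, imbalance arithmetic, and PR/ROC areas vs. oracles."""

import numpy as np
import pytest

from mirsite.metrics import (
    ConfusionCounts,
    ThresholdPolicy,
    auprc,
    auroc,
    confusion,
    f1,
    precision,
    precision_from_rates,
    pr_curve,
    recall,
    roc_curve,
    threshold_report,
)


def brute_force_average_precision(scores, labels):
    """AP as the sum of precision-weighted recall increments over every
    distinct score threshold (ties grouped), enumerated explicitly."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    P = labels.sum()
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        rec_t = tp / P
        prec_t = tp / int(pred.sum())
        ap += (rec_t - prev_recall) * prec_t
        prev_recall = rec_t
    return ap


def brute_force_roc_auc(scores, labels):
    """AUC as the Mann-Whitney U statistic with ties counted half."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_scorer_has_no_errors(self):
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        c = confusion(scores, labels, 0.5)
        assert (c.FP, c.FN) == (0, 0)

    def test_threshold_zero_predicts_everything_positive(self):
        labels = np.array([1, 0, 1, 0])
        c = confusion(np.array([0.3, 0.1, 0.9, 0.0]), labels, 0.0)
        assert (c.TN, c.FN) == (0, 0)

    def test_ties_count_positive(self):
        c = confusion(np.array([0.5, 0.5]), np.array([1, 0]), 0.5)
        assert (c.TP, c.FP) == (1, 1)

    def test_random_case_matches_counting_loop(self, rng):
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        thr = 0.37
        c = confusion(scores, labels, thr)
        tp = sum(1 for s, y in zip(scores, labels) if s >= thr and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= thr and y == 0)
        fn = sum(1 for s, y in zip(scores, labels) if s < thr and y == 1)
        tn = sum(1 for s, y in zip(scores, labels) if s < thr and y == 0)
        assert (c.TP, c.FP, c.TN, c.FN) == (tp, fp, tn, fn)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros(3), np.zeros(4), 0.5)


class TestPointMetrics:
    def test_recall_from_counts(self):
        assert recall(ConfusionCounts(TP=285, FP=0, TN=0, FN=1715)) == pytest.approx(0.1425)

    def test_precision_from_counts(self):
        # 285 true positives against 39 false positives at a 1:1 ratio
        assert precision(ConfusionCounts(TP=285, FP=39, TN=1961, FN=1715)) == pytest.approx(
            0.8796, abs=5e-5
        )

    def test_undefined_precision_flagged_not_raised(self):
        assert np.isnan(precision(ConfusionCounts(TP=0, FP=0, TN=5, FN=5)))

    def test_f1_is_harmonic_mean(self):
        c = ConfusionCounts(TP=30, FP=10, TN=50, FN=10)
        p, r = precision(c), recall(c)
        assert f1(c) == pytest.approx(2 * p * r / (p + r))


class TestPrecisionFromRates:
    def test_published_seed_rates_reproduce_precision(self):
        assert precision_from_rates(0.1425, 0.0195, 1) == pytest.approx(0.8796, abs=5e-5)

    def test_zero_fpr_gives_perfect_precision(self):
        assert precision_from_rates(0.3, 0.0, 100) == 1.0

    def test_all_zero_rates_undefined(self):
        assert np.isnan(precision_from_rates(0.0, 0.0, 10))

    def test_agrees_with_realized_counts(self, rng):
        for _ in range(50):
            P = int(rng.integers(10, 200))
            k = int(rng.integers(1, 20))
            tp = int(rng.integers(0, P + 1))
            fp = int(rng.integers(0, k * P + 1))
            if tp == 0 and fp == 0:
                continue
            c = ConfusionCounts(TP=tp, FP=fp, TN=k * P - fp, FN=P - tp)
            assert precision_from_rates(tp / P, fp / (k * P), k) == pytest.approx(
                precision(c)
            )


class TestCurves:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert auprc(scores, labels) == 1.0
        assert auroc(scores, labels) == 1.0

    def test_constant_scores_limits(self):
        labels = np.array([1] * 5 + [0] * 15)
        scores = np.full(20, 0.4)
        assert auprc(scores, labels) == pytest.approx(5 / 20)
        assert auroc(scores, labels) == pytest.approx(0.5)

    def test_areas_match_exhaustive_enumeration(self, rng):
        for _ in range(20):
            labels = rng.integers(0, 2, 20)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(20), 2)  # ties likely
            assert auprc(scores, labels) == pytest.approx(
                brute_force_average_precision(scores, labels), abs=1e-12
            )
            assert auroc(scores, labels) == pytest.approx(
                brute_force_roc_auc(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pr_curve(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_recall_axis_non_decreasing(self, rng):
        labels = rng.integers(0, 2, 30)
        labels[0], labels[1] = 0, 1
        scores = rng.random(30)
        assert (np.diff(pr_curve(scores, labels).x) >= 0).all()
        assert (np.diff(roc_curve(scores, labels).x) >= 0).all()


class TestThresholdReport:
    def test_policy_rows_present(self, rng):
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        scores = rng.random(40)
        report = threshold_report(scores, labels)
        named = report.rows[report.rows["tag"] != "grid"]
        assert sorted(named["threshold"]) == [0.1, 0.5]

    def test_all_positive_scored_one(self):
        labels = np.ones(10)
        scores = np.ones(10)
        report = threshold_report(scores, labels)
        named = report.rows[report.rows["tag"] != "grid"]
        assert (named["precision"] == 1.0).all()
        assert (named["recall"] == 1.0).all()

    def test_rows_match_manual_composition(self, rng):
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        scores = rng.random(60)
        report = threshold_report(scores, labels)
        for _, row in report.rows[report.rows["tag"] != "grid"].iterrows():
            c = confusion(scores, labels, row["threshold"])
            assert row["precision"] == pytest.approx(precision(c), nan_ok=True)
            assert row["recall"] == pytest.approx(recall(c), nan_ok=True)
            assert row["f1"] == pytest.approx(f1(c), nan_ok=True)

    def test_policy_ordering_validated(self):
        with pytest.raises(ValueError):
            ThresholdPolicy(normal=0.5, strict=0.1)
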