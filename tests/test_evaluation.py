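"""Metric definitions checked against brute-force oracles and hand arithmetic."""

import numpy as np
import pytest

from actin.evaluation import (
    UndefinedMetricError,
    confusion_and_error,
    pearson_per_instance,
    pr_auc,
    roc_auc,
    up_down_scores,
    weighted_aggregate,
)
from actin.expression import ExpressionLabel, label, step_function
from actin.reference import ACTIN_ALL_REPORTED, metric_columns


def roc_auc_oracle(labels, scores):
    """All-pairs concordance count with half credit for ties."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class _FakeSample:
    def __init__(self, logFC, instance="i0"):
        self.logFC = logFC
        self.target = float(step_function(logFC))
        self.true_label = label(logFC)
        self.instance_id = instance


def test_roc_auc_hand_example():
    assert roc_auc([1, 0, 1, 0], [0.8, 0.7, 0.6, 0.5]) == pytest.approx(0.75)


def test_roc_auc_perfect_separation_and_all_ties():
    assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
    assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5


def test_roc_auc_single_class_undefined():
    with pytest.raises(UndefinedMetricError):
        roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


def test_roc_auc_matches_concordance_oracle_on_random_instances():
    rng = np.random.default_rng(11)
    for _ in range(200):
        n = int(rng.integers(4, 50))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.normal(size=n), 1)  # rounding induces ties
        assert roc_auc(labels, scores) == pytest.approx(
            roc_auc_oracle(labels, scores), abs=1e-12)


def test_pr_auc_hand_examples():
    # single positive ranked last of 4 -> average precision 1/4
    assert pr_auc([0, 0, 0, 1], [0.9, 0.8, 0.7, 0.1]) == pytest.approx(0.25)
    assert pr_auc([0, 1, 1], [0.1, 0.8, 0.9]) == 1.0
    assert pr_auc([1, 1], [0.3, 0.9]) == 1.0  # all positives -> precision 1
    with pytest.raises(UndefinedMetricError):
        pr_auc([0, 0], [0.1, 0.2])


def test_up_down_scores_builds_complementary_problems():
    samples = [_FakeSample(x) for x in (2.0, -2.0, 0.5, 1.5)]
    preds = np.array([0.9, -0.8, 0.0, 0.7])
    (up_l, up_s), (down_l, down_s) = up_down_scores(samples, preds)
    np.testing.assert_array_equal(up_l, [1, 0, 0, 1])
    np.testing.assert_array_equal(down_l, [0, 1, 0, 0])
    np.testing.assert_array_equal(down_s, -preds)
    with pytest.raises(ValueError):
        up_down_scores(samples, preds[:2])


def test_up_down_auc_antisymmetry_under_score_negation():
    rng = np.random.default_rng(12)
    samples = [_FakeSample(x) for x in rng.normal(scale=1.5, size=100)]
    preds = rng.normal(size=100)
    (up_l, up_s), (down_l, down_s) = up_down_scores(samples, preds)
    (up_l2, up_s2), (down_l2, down_s2) = up_down_scores(samples, -preds)
    assert roc_auc(up_l, up_s) == pytest.approx(1 - roc_auc(up_l2, up_s2))
    assert roc_auc(down_l, down_s) == pytest.approx(1 - roc_auc(down_l2, down_s2))


def test_pearson_perfect_and_antiperfect():
    samples = [_FakeSample(x, "i0") for x in (2.0, -1.5, 0.3, 0.8)]
    targets = np.array([s.target for s in samples])
    assert pearson_per_instance(samples, targets)[0] == pytest.approx(1.0)
    assert pearson_per_instance(samples, -targets)[0] == pytest.approx(-1.0)


def test_pearson_unweighted_mean_over_instances():
    # instance a: r = 1 (3-gene exact match); instance b: hand-computed r = 0.5
    sa = [_FakeSample(x, "a") for x in (0.1, 0.5, 0.9)]
    pa = np.array([s.target for s in sa])
    sb = [_FakeSample(x, "b") for x in (0.1, 0.5, 0.9)]
    tb = np.array([s.target for s in sb])
    # construct predictions with known correlation 0.5 to tb is fiddly; use
    # a fixed triple whose r we computed by hand against tb's ordering
    pb = np.array([tb[0], tb[2], tb[1]])
    r_b = np.corrcoef(pb, tb)[0, 1]
    mean_r, excluded = pearson_per_instance(sa + sb, np.concatenate([pa, pb]))
    assert excluded == 0
    assert mean_r == pytest.approx((1.0 + r_b) / 2)


def test_pearson_zero_variance_instance_excluded():
    sa = [_FakeSample(x, "a") for x in (0.1, 0.5)]
    sb = [_FakeSample(x, "b") for x in (0.2, 0.6)]
    preds = np.array([0.5, 0.5, 0.1, 0.9])  # instance a constant -> excluded
    mean_r, excluded = pearson_per_instance(sa + sb, preds)
    assert excluded == 1


def test_confusion_partitions_pairs_and_counts_opposites():
    logfc = [2.0, 2.0, -2.0, -2.0, 2.0, 0.0, 0.0, 0.5, -0.5, 0.2]
    samples = [_FakeSample(x) for x in logfc]
    # predictions: two completely opposite calls among the 5 Up/Down truths
    preds = [0.9, -0.9, 0.8, -0.8, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
    counts, err = confusion_and_error(samples, np.array(preds))
    assert counts.sum() == 10
    assert err == pytest.approx(0.4)  # 2 opposite / 5 Up-Down truths


def test_confusion_perfect_and_flipped():
    samples = [_FakeSample(x) for x in (2.0, -2.0, 0.0)]
    perfect = np.array([s.target for s in samples])
    _, err = confusion_and_error(samples, perfect)
    assert err == 0.0
    _, err_flipped = confusion_and_error(samples, -perfect)
    assert err_flipped == 1.0


def test_confusion_all_pairs_denominator_flag():
    samples = [_FakeSample(x) for x in (2.0, -2.0, 0.0, 0.0)]
    preds = np.array([-0.9, 0.9, 0.0, 0.0])
    _, err = confusion_and_error(samples, preds, denominator="all")
    assert err == pytest.approx(0.5)


def test_weighted_aggregate_arithmetic():
    assert weighted_aggregate([0.5, 1.0], [1, 3])[0] == pytest.approx(0.875)
    assert weighted_aggregate([0.2, 0.4], [2, 2])[0] == pytest.approx(0.3)
    with pytest.raises(ValueError):
        weighted_aggregate([0.5], [0])


def test_weighted_aggregate_reproduces_reported_summary_row():
    """The published per-cell-line table aggregates to the reported ALL row."""
    sizes, cols = metric_columns()
    for metric, reported in ACTIN_ALL_REPORTED.items():
        mean, _ = weighted_aggregate(cols[metric], sizes)
        assert round(mean, 4) == reported
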