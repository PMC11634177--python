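"""Evaluation metrics for chemical-perturbation prediction.

A trained model is scored on held-out pairs four ways:

* **Up/Down ROC-AUC and PR-AUC** — two one-vs-rest ranking problems.  The Up
  problem treats truly up-regulated genes (logFC > 1) as positives scored by
  the prediction s; the Down problem treats down-regulated genes as positives
  scored by -s.
* **Pearson correlation** — computed per perturbation instance between
  predictions and SF-mapped targets over that instance's genes, then averaged
  (a pooled variant is available).
* **Confusion matrix and error rate** — predictions are classified through
  the same thresholds as the targets; the error rate is the fraction of
  truly Up/Down pairs predicted with the *opposite* sign.
* **Weighted aggregation** — per-cell-line metrics are combined into an
  "ALL" summary weighted by test sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .expression import DEFAULT_SF, ExpressionLabel, StepFunctionParams, predicted_label

_LABELS = (ExpressionLabel.UP, ExpressionLabel.DOWN, ExpressionLabel.NONE)


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given label composition."""


def roc_auc(labels, scores) -> float:
    """ROC-AUC in Mann-Whitney form (ties get half credit)."""
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise UndefinedMetricError("ROC-AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def pr_auc(labels, scores) -> float:
    """Precision-recall AUC in average-precision (step interpolation) form."""
    labels = np.asarray(labels).astype(int)
    if labels.sum() == 0:
        raise UndefinedMetricError("PR-AUC needs at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=np.float64)))


def up_down_scores(samples, predictions):
    """Build the Up and Down binary ranking problems.

    Returns ((up_labels, up_scores), (down_labels, down_scores)); the Down
    problem negates the score so that stronger predicted down-regulation
    ranks higher.
    """
    predictions = np.asarray(predictions, dtype=np.float64)
    if len(samples) != len(predictions):
        raise ValueError(f"{len(samples)} samples vs {len(predictions)} predictions")
    truth = np.array([s.true_label for s in samples], dtype=object)
    up = ((truth == ExpressionLabel.UP).astype(int), predictions)
    down = ((truth == ExpressionLabel.DOWN).astype(int), -predictions)
    return up, down


def pearson_per_instance(samples, predictions, pooled: bool = False):
    """Mean Pearson r between predictions and targets.

    Per-instance mode (default) computes r over each perturbation instance's
    genes and averages unweighted; instances with zero variance on either
    side are excluded and counted.  Returns (mean_r, n_excluded).
    """
    predictions = np.asarray(predictions, dtype=np.float64)
    targets = np.array([s.target for s in samples])
    if pooled:
        if np.std(targets) == 0 or np.std(predictions) == 0:
            raise UndefinedMetricError("zero variance in pooled Pearson")
        return float(np.corrcoef(predictions, targets)[0, 1]), 0
    groups: dict = {}
    for i, s in enumerate(samples):
        groups.setdefault(s.instance_id, []).append(i)
    rs, excluded = [], 0
    for idx in groups.values():
        if len(idx) < 2:
            excluded += 1
            continue
        p, t = predictions[idx], targets[idx]
        if np.std(p) == 0 or np.std(t) == 0:
            excluded += 1
            continue
        rs.append(np.corrcoef(p, t)[0, 1])
    if not rs:
        raise UndefinedMetricError("no instance with computable Pearson r")
    return float(np.mean(rs)), excluded


def confusion_and_error(samples, predictions,
                        sf_params: StepFunctionParams = DEFAULT_SF,
                        denominator: str = "updown"):
    """3x3 confusion counts (pred x true over Up/Down/None) and error rate.

    The error rate counts completely opposite calls (pred Up on true Down and
    vice versa).  ``denominator`` selects the base: 'updown' (pairs whose true
    label is Up or Down; default) or 'all' (every test pair).
    """
    predictions = np.asarray(predictions, dtype=np.float64)
    if len(samples) != len(predictions):
        raise ValueError("length mismatch between samples and predictions")
    index = {lab: k for k, lab in enumerate(_LABELS)}
    counts = np.zeros((3, 3), dtype=int)
    for s, p in zip(samples, predictions):
        counts[index[predicted_label(float(p), sf_params)], index[s.true_label]] += 1
    opposite = counts[index[ExpressionLabel.UP], index[ExpressionLabel.DOWN]] \
        + counts[index[ExpressionLabel.DOWN], index[ExpressionLabel.UP]]
    if denominator == "updown":
        base = counts[:, index[ExpressionLabel.UP]].sum() + counts[:, index[ExpressionLabel.DOWN]].sum()
    elif denominator == "all":
        base = counts.sum()
    else:
        raise ValueError("denominator must be 'updown' or 'all'")
    if base == 0:
        raise UndefinedMetricError("no truly Up/Down pairs — error rate undefined")
    return counts, float(opposite / base)


def weighted_aggregate(values, sample_sizes):
    """Sample-size-weighted mean of per-model metrics plus the unweighted sd.

    Returns (weighted_mean, unweighted_sd); this is the "ALL" aggregation
    over per-cell-line models.
    """
    values = np.asarray(values, dtype=np.float64)
    weights = np.asarray(sample_sizes, dtype=np.float64)
    if values.shape != weights.shape or values.ndim != 1:
        raise ValueError("values and sample_sizes must be equal-length 1-d")
    if np.any(weights <= 0) or weights.sum() == 0:
        raise ValueError("sample sizes must be positive")
    mean = float(np.sum(weights * values) / weights.sum())
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return mean, sd


@dataclass
class EvaluationReport:
    cell_line: str
    n_instances: int
    n_pairs: int
    roc_auc_up: float
    pr_auc_up: float
    roc_auc_down: float
    pr_auc_down: float
    mean_pearson: float
    pearson_excluded: int
    confusion: np.ndarray          # 3x3, pred x true, order Up/Down/None
    error_rate: float
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in self.__dict__.items()}
        return d


def evaluate_pairs(samples, predictions,
                   sf_params: StepFunctionParams = DEFAULT_SF,
                   cell_line: str = "") -> EvaluationReport:
    """Full metric panel for one model's held-out pairs."""
    (up_l, up_s), (down_l, down_s) = up_down_scores(samples, predictions)
    mean_r, excluded = pearson_per_instance(samples, predictions)
    counts, err = confusion_and_error(samples, predictions, sf_params)
    undefined = []

    def _try(fn, labels, scores, name):
        try:
            return fn(labels, scores)
        except UndefinedMetricError:
            undefined.append(name)
            return float("nan")

    return EvaluationReport(
        cell_line=cell_line or samples[0].cell_line,
        n_instances=len({s.instance_id for s in samples}),
        n_pairs=len(samples),
        roc_auc_up=_try(roc_auc, up_l, up_s, "roc_auc_up"),
        pr_auc_up=_try(pr_auc, up_l, up_s, "pr_auc_up"),
        roc_auc_down=_try(roc_auc, down_l, down_s, "roc_auc_down"),
        pr_auc_down=_try(pr_auc, down_l, down_s, "pr_auc_down"),
        mean_pearson=mean_r,
        pearson_excluded=excluded,
        confusion=counts,
        error_rate=err,
        extra={"undefined_metrics": undefined} if undefined else {},
    )
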