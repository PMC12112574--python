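"""Threshold-free and thresholded metrics, bootstrap confidence intervals,
paired model comparison, calibration and the Brier score.

AUPRC is average precision (step-wise summation — trapezoids over PR space
are biased); AUROC is the trapezoidal area with tied scores grouped.  All
confidence intervals are percentile bootstrap over resampled
(score, label) pairs, n = 100 by default.  A prediction is called positive
when score >= threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from ._common import rng_from_seed

logger = logging.getLogger(__name__)


def confusion_metrics(scores, labels, threshold: float) -> dict:
    """Sensitivity, specificity, PPV, NPV, Youden index and accuracy at a
    threshold.  Division-by-zero cells yield NaN (undefined), never 0."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())

    def ratio(a, b):
        return a / b if b > 0 else math.nan

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    out = {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "youden": sens + spec - 1
        if not (math.isnan(sens) or math.isnan(spec))
        else math.nan,
        "accuracy": ratio(tp + tn, tp + fp + fn + tn),
    }
    return out


def pr_curve_auprc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """(precision, recall, AUPRC) with AUPRC as average precision."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _require_both_classes(labels)
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # group tied scores: keep the last index of each distinct score
    distinct = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[distinct], fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / labels.sum()
    auprc = float(average_precision_score(labels, scores))
    return precision, recall, auprc


def roc_curve_auroc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """(fpr, tpr, AUROC); ties grouped, trapezoidal area."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _require_both_classes(labels)
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    distinct = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tp[distinct] / labels.sum()]
    fpr = np.r_[0.0, fp[distinct] / (len(labels) - labels.sum())]
    auroc = float(roc_auc_score(labels, scores))
    return fpr, tpr, auroc


def _require_both_classes(labels: np.ndarray) -> None:
    if labels.sum() in (0, len(labels)):
        raise ValueError("metric undefined with a single-class label set")


def bootstrap_ci(
    metric_fn,
    scores,
    labels,
    n: int = 100,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Percentile bootstrap over resampled (score, label) pairs.

    Resamples containing a single class are skipped (and logged) when the
    metric needs both classes.  Returns (point, lower, upper).
    """
    if n < 2:
        raise ValueError("bootstrap needs n >= 2")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    point = float(metric_fn(scores, labels))
    rng = rng_from_seed(seed)
    stats, skipped = [], 0
    for _ in range(n):
        idx = rng.integers(0, len(scores), size=len(scores))
        try:
            stats.append(float(metric_fn(scores[idx], labels[idx])))
        except ValueError:
            skipped += 1
    if skipped:
        logger.info("bootstrap: skipped %d degenerate resamples", skipped)
    if not stats:
        raise ValueError("all bootstrap resamples degenerate")
    alpha = (1.0 - level) / 2.0
    lower = float(np.quantile(stats, alpha))
    upper = float(np.quantile(stats, 1.0 - alpha))
    return point, min(lower, point), max(upper, point)


def compare_auprc(
    scores_a, scores_b, labels, n: int = 100, seed: int = 0
) -> tuple[float, float]:
    """Paired bootstrap AUPRC comparison.

    The same resample indices are applied to both models; the two-sided
    p-value is ``2 * min(P(delta <= 0), P(delta >= 0))`` over the bootstrap
    distribution, floored at ``1 / (n + 1)`` and capped at 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("score vectors and labels must be aligned")
    delta = float(
        average_precision_score(labels, scores_a)
        - average_precision_score(labels, scores_b)
    )
    rng = rng_from_seed(seed)
    deltas = []
    for _ in range(n):
        idx = rng.integers(0, len(labels), size=len(labels))
        yb = labels[idx]
        if yb.sum() in (0, len(yb)):
            continue
        deltas.append(
            average_precision_score(yb, scores_a[idx])
            - average_precision_score(yb, scores_b[idx])
        )
    deltas = np.asarray(deltas)
    frac_le = float((deltas <= 0).mean()) if len(deltas) else 0.5
    frac_ge = float((deltas >= 0).mean()) if len(deltas) else 0.5
    p = 2.0 * min(frac_le, frac_ge)
    p = min(max(p, 1.0 / (n + 1)), 1.0)
    return delta, p


@dataclass
class CalibrationReport:
    bin_edges: np.ndarray
    bin_mean_predicted: np.ndarray
    bin_event_rate: np.ndarray
    bin_counts: np.ndarray
    brier: float


def calibration(scores, labels, n_bins: int = 10) -> CalibrationReport:
    """Equal-width reliability bins over [0, 1] plus the Brier score.

    Empty bins are omitted from the per-bin arrays.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("calibration expects probabilities in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(scores, edges[1:-1]), 0, n_bins - 1)
    mean_pred, event_rate, counts = [], [], []
    for b in range(n_bins):
        m = which == b
        if not m.any():
            continue
        mean_pred.append(float(scores[m].mean()))
        event_rate.append(float(labels[m].mean()))
        counts.append(int(m.sum()))
    brier = float(np.mean((scores - labels) ** 2))
    return CalibrationReport(
        bin_edges=edges,
        bin_mean_predicted=np.asarray(mean_pred),
        bin_event_rate=np.asarray(event_rate),
        bin_counts=np.asarray(counts),
        brier=brier,
    )


def evaluation_report(
    scores_by_model: dict[str, np.ndarray],
    labels: np.ndarray,
    thresholds: dict[str, float],
    horizon: int,
    n_boot: int = 100,
    seed: int = 0,
) -> dict:
    """Full per-horizon report: AUROC/AUPRC/thresholded metrics with 95%
    bootstrap CIs, confusion matrix at threshold, calibration + Brier."""
    labels = np.asarray(labels).astype(int)
    report: dict = {"horizon_hours": horizon, "models": {}}
    for name, scores in scores_by_model.items():
        scores = np.asarray(scores, dtype=float)
        thr = thresholds[name]
        entry: dict = {"threshold": thr}
        entry["auprc"] = _with_ci(
            lambda s, y: average_precision_score(y, s), scores, labels, n_boot, seed)
        entry["auroc"] = _with_ci(
            lambda s, y: roc_auc_score(y, s), scores, labels, n_boot, seed)
        cm = confusion_metrics(scores, labels, thr)
        entry["confusion"] = {k: cm[k] for k in ("tp", "fp", "fn", "tn")}
        for metric in ("sensitivity", "specificity", "ppv", "npv", "youden"):
            entry[metric] = _with_ci(
                _thresholded(metric, thr), scores, labels, n_boot, seed)
        cal = calibration(scores, labels)
        entry["brier"] = cal.brier
        entry["calibration"] = {
            "bin_mean_predicted": cal.bin_mean_predicted.tolist(),
            "bin_event_rate": cal.bin_event_rate.tolist(),
            "bin_counts": cal.bin_counts.tolist(),
        }
        report["models"][name] = entry
    return report


def _thresholded(metric: str, threshold: float):
    def fn(scores, labels):
        value = confusion_metrics(scores, labels, threshold)[metric]
        if math.isnan(value):
            raise ValueError(f"{metric} undefined on this resample")
        return value

    return fn


def _with_ci(metric_fn, scores, labels, n_boot, seed) -> dict:
    point, lo, hi = bootstrap_ci(metric_fn, scores, labels, n=n_boot, seed=seed)
    return {"point": point, "ci95": [lo, hi]}
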