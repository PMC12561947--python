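"""Classification metric suite: confusion metrics, Brier score, ROC/AUC,
and the paired t-test used to compare per-fold scores.

Cough is the positive class throughout.  Ratios with a zero denominator are
reported as 0.0 and flagged rather than dropped, so aggregates over folds
remain well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    brier: float
    auc: float
    undefined: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "specificity": self.specificity,
            "f1": self.f1, "brier": self.brier, "auc": self.auc,
            "undefined": list(self.undefined),
        }


def _safe_ratio(num, den, name, undefined):
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def compute_metrics(y_true, y_pred, y_prob) -> MetricsReport:
    """Confusion-matrix metrics at the given hard predictions.

    Parameters
    ----------
    y_true : binary labels (1 = cough)
    y_pred : binary hard predictions
    y_prob : predicted probability of the cough class (used for the Brier
        score and AUC)
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty input")
    if not (y_true.shape == y_pred.shape == y_prob.shape):
        raise ValueError("y_true, y_pred, y_prob must have equal lengths")

    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))

    undefined: list[str] = []
    accuracy = (tp + tn) / y_true.size
    precision = _safe_ratio(tp, tp + fp, "precision", undefined)
    recall = _safe_ratio(tp, tp + fn, "recall", undefined)
    specificity = _safe_ratio(tn, tn + fp, "specificity", undefined)
    f1 = _safe_ratio(2 * precision * recall, precision + recall, "f1", undefined)
    brier = float(np.mean((y_prob - y_true) ** 2))
    if len(np.unique(y_true)) == 2:
        auc = roc_auc(y_true, y_prob)[0]
    else:
        undefined.append("auc")
        auc = 0.0
    return MetricsReport(tp, fp, fn, tn, accuracy, precision, recall,
                         specificity, f1, brier, auc, undefined)


def roc_auc(y_true, scores):
    """Rank-based AUC plus the full ROC curve.

    The AUC equals the probability that a random positive outscores a
    random negative, ties counting one half (Mann-Whitney statistic).

    Returns
    -------
    auc : float
    curve : (fpr, tpr) arrays over all score thresholds, (0,0) -> (1,1)
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")

    ranks = stats.rankdata(scores)  # average ranks handle ties
    auc = (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    sorted_true = y_true[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_true == 1)
    fps = np.cumsum(sorted_true == 0)
    # keep the last point of each tied-score run
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return float(auc), (fpr, tpr)


def paired_t_test(a, b):
    """Two-sided paired t-test on per-fold scores.

    t = mean(d) / (sd(d)/sqrt(n)) with the sample standard deviation
    (n-1 denominator); p from the t distribution with n-1 degrees of
    freedom.  Identical vectors (zero-variance differences) are rejected as
    degenerate rather than reported as t = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired_t_test needs two equal-length vectors, n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate paired test: zero-variance differences")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def aggregate_fold_metric(values) -> tuple[float, float]:
    """Mean and sample std (ddof=1; 0 for a single fold) of per-fold scores."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no fold values to aggregate")
    std = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), std
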