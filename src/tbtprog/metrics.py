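"""ROC metrics: mid-rank AUC, accuracy / diagnostic odds ratio, and the
DeLong test for correlated ROC curves.

The DeLong machinery follows the structural-components formulation: the
AUC is the Mann-Whitney U statistic, each case and control contributes a
placement value, and the empirical covariance of those placements across
paired score vectors gives the variance of an AUC difference, so two
models evaluated on the same knees can be compared without independence
assumptions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .errors import ParameterError, UndefinedMetricError

__all__ = [
    "auc",
    "youden_threshold",
    "acc_dor",
    "roc_coordinates",
    "delong_variance",
    "delong_compare",
    "DeLongComparison",
]


def _check_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    if not (pos.any() and neg.any()):
        raise UndefinedMetricError("both outcome classes must be present")
    if not np.all(pos | neg):
        raise ParameterError("labels must be 0/1")
    return pos, neg


def auc(labels, scores) -> float:
    """Mid-rank (Mann-Whitney) AUC; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_classes(labels)
    if scores.shape != np.asarray(labels).shape:
        raise ParameterError("labels and scores must have the same length")
    r = rankdata(scores)
    n1, n0 = int(pos.sum()), int(neg.sum())
    return float((r[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def youden_threshold(labels, scores) -> float:
    """Score cutoff maximising Youden's J = sensitivity + specificity - 1
    (first maximum along decreasing thresholds)."""
    from sklearn.metrics import roc_curve

    _check_classes(labels)
    fpr, tpr, thresholds = roc_curve(labels, scores)
    j = tpr - fpr
    idx = int(np.argmax(j))
    thr = thresholds[idx]
    if np.isinf(thr):  # the "predict nothing positive" corner
        thr = float(np.max(scores))
    return float(thr)


def acc_dor(labels, scores, threshold_rule="youden") -> tuple[float, float, float]:
    """Accuracy and diagnostic odds ratio at a score cutoff.

    ``threshold_rule`` is ``"youden"`` (J-optimal on this scoring set) or a
    fixed numeric cutoff.  DOR = (TP*TN)/(FP*FN) with the Haldane 0.5
    continuity correction applied to all cells when any cell is zero, so a
    perfect classifier reports a finite DOR.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    _check_classes(labels)
    if threshold_rule == "youden":
        thr = youden_threshold(labels, scores)
    else:
        thr = float(threshold_rule)
    pred = scores >= thr
    tp = float(np.sum(pred & (labels == 1)))
    tn = float(np.sum(~pred & (labels == 0)))
    fp = float(np.sum(pred & (labels == 0)))
    fn = float(np.sum(~pred & (labels == 1)))
    acc = (tp + tn) / labels.size
    if min(tp, tn, fp, fn) == 0:
        tp, tn, fp, fn = tp + 0.5, tn + 0.5, fp + 0.5, fn + 0.5
    dor = (tp * tn) / (fp * fn)
    return float(acc), float(dor), float(thr)


def roc_coordinates(labels, scores):
    """ROC curve coordinates as a DataFrame (fpr, tpr, threshold), for
    plotting or export."""
    import pandas as pd
    from sklearn.metrics import roc_curve

    _check_classes(labels)
    fpr, tpr, thr = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def _midrank(x: np.ndarray) -> np.ndarray:
    return rankdata(x, method="average")


def _placements(labels, scores) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the case and control structural components (placements)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_classes(labels)
    x, y_ = scores[pos], scores[neg]
    m, n = x.size, y_.size
    tz = _midrank(np.concatenate([x, y_]))
    tx = _midrank(x)
    ty = _midrank(y_)
    a = float((tz[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    v01 = (tz[:m] - tx) / n  # per-case placements
    v10 = 1.0 - (tz[m:] - ty) / m  # per-control placements
    return a, v01, v10


def delong_variance(labels, scores) -> tuple[float, float]:
    """AUC and its DeLong variance estimate for a single score vector."""
    a, v01, v10 = _placements(labels, scores)
    m, n = v01.size, v10.size
    var = np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n
    return a, float(var)


@dataclass
class DeLongComparison:
    """Paired comparison of two ROC curves on the same knees."""

    auc_a: float
    auc_b: float
    auc_diff: float
    se_diff: float
    z: float
    p_value: float
    ci: tuple[float, float]


def delong_compare(labels, scores_a, scores_b, alpha: float = 0.05) -> DeLongComparison:
    """Two-sided DeLong test on the AUC difference of paired score vectors.

    The test statistic is antisymmetric in (a, b); identical score vectors
    give diff = 0 and p = 1 exactly.
    """
    labels = np.asarray(labels)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if not (labels.shape == scores_a.shape == scores_b.shape):
        raise ParameterError("labels, scores_a and scores_b must be paired (equal length)")
    a_a, v01_a, v10_a = _placements(labels, scores_a)
    a_b, v01_b, v10_b = _placements(labels, scores_b)
    m, n = v01_a.size, v10_a.size

    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    var_diff = (
        s01[0, 0] / m + s01[1, 1] / m - 2 * s01[0, 1] / m
        + s10[0, 0] / n + s10[1, 1] / n - 2 * s10[0, 1] / n
    )
    diff = a_a - a_b
    if var_diff <= 1e-15:
        z = 0.0
        p = 1.0 if abs(diff) < 1e-12 else 0.0
        se = 0.0
    else:
        se = float(np.sqrt(var_diff))
        z = diff / se
        p = float(2.0 * norm.sf(abs(z)))
    q = norm.ppf(1 - alpha / 2.0)
    return DeLongComparison(
        auc_a=a_a,
        auc_b=a_b,
        auc_diff=float(diff),
        se_diff=se,
        z=float(z),
        p_value=p,
        ci=(float(diff - q * se), float(diff + q * se)),
    )
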