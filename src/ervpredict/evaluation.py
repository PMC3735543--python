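"""Performance evaluation: ROC/AUC, threshold metrics, CV summaries, statistics.

Conventions: a record is called positive when its likelihood is >= the
threshold. Sensitivity = TPR, specificity = 1 - FPR, all reported as
percentages. The proportions test is the continuity-corrected chi-square
test of equal proportions on a 2x2 table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn import metrics as skmetrics

from ervpredict.ensemble import CvPlan, EnsembleModel, consolidate
from ervpredict import mlp_core

# Log-spaced bin edges matching the resolution needs of heavily skewed
# likelihood distributions (most scores pile up near 0).
LOG_BIN_EDGES = (0.0, 1e-4, 1e-3, 1e-2, 0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class RocCurve:
    thresholds: np.ndarray  # descending
    fpr_points: np.ndarray
    tpr_points: np.ndarray
    auc: float


@dataclass
class ThresholdReport:
    tau: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> float:
        """True positive rate, percent."""
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def fpr(self) -> float:
        """False positive rate, percent."""
        return 100.0 * self.fp / (self.fp + self.tn)

    @property
    def sensitivity(self) -> float:
        return self.tpr

    @property
    def specificity(self) -> float:
        return 100.0 - self.fpr


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    if not (np.any(labels == 1) and np.any(labels == 0)):
        raise ValueError("both classes must be present to evaluate a classifier")
    return scores, labels


def roc_and_auc(scores, labels) -> RocCurve:
    """ROC curve sweeping all distinct scores; AUC by trapezoidal integration.

    Tied scores are grouped at a single threshold step, so the curve starts
    at (0, 0) and ends at (1, 1) with non-decreasing FPR and TPR.
    """
    scores, labels = _check_scores_labels(scores, labels)
    fpr, tpr, thresholds = skmetrics.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(skmetrics.auc(fpr, tpr))
    return RocCurve(thresholds=thresholds, fpr_points=fpr, tpr_points=tpr, auc=auc)


def threshold_report(scores, labels, tau: float) -> ThresholdReport:
    """Confusion counts and rates when calling positive at score >= tau."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    scores, labels = _check_scores_labels(scores, labels)
    calls = scores >= tau
    return ThresholdReport(
        tau=tau,
        tp=int(np.sum(calls & (labels == 1))),
        fp=int(np.sum(calls & (labels == 0))),
        tn=int(np.sum(~calls & (labels == 0))),
        fn=int(np.sum(~calls & (labels == 1))),
    )


def cv_performance(ensemble: EnsembleModel, plan: CvPlan, data) -> tuple[float, float, list[float]]:
    """Mean and sample standard deviation of the per-split held-out AUCs.

    For each split, that split's reinitialized members are consolidated on
    the split's test cases only, and one ROC/AUC is computed. A test fold
    missing one class is excluded with a warning.
    """
    X, t = mlp_core._as_xy(data)
    aucs = []
    for s, split in enumerate(plan.splits):
        te = split["test_idx"]
        labels = t[te]
        if not (np.any(labels == 1) and np.any(labels == 0)):
            warnings.warn(f"split {s}: test fold misses a class; AUC undefined and excluded", stacklevel=2)
            continue
        scores = consolidate(ensemble, X[te], ensemble.member_mask(s))
        aucs.append(roc_and_auc(scores, labels).auc)
    if not aucs:
        raise ValueError("no split produced a defined AUC")
    mean = float(np.mean(aucs))
    sd = float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0
    return mean, sd, aucs


def prop_equality_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-sided test of equal proportions k1/n1 vs k2/n2.

    Chi-square on the 2x2 table with Yates continuity correction; returns
    (statistic, p). A degenerate margin (all successes or all failures
    pooled) is reported as p = 1 with a warning.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("success counts must satisfy 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table.sum(axis=0) == 0):
        warnings.warn("degenerate 2x2 margin: proportions are trivially equal", stacklevel=2)
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=True)
    return float(res.statistic), float(res.pvalue)


def two_sample_t(a, b) -> tuple[float, float]:
    """Classic pooled-variance Student's t test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            warnings.warn("zero pooled variance with equal means: t = 0, p = 1", stacklevel=2)
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means: p -> 0", stacklevel=2)
        return float("inf") if np.mean(a) > np.mean(b) else float("-inf"), 0.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def output_histogram(scores, bin_edges=LOG_BIN_EDGES) -> np.ndarray:
    """Percentage of scores per bin; bins are [e_i, e_{i+1}), last bin closed.

    Defaults to log-spaced edges so the crowded low end of a skewed
    likelihood distribution stays resolved.
    """
    scores = np.asarray(scores, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if edges[0] > 0 or edges[-1] < 1:
        raise ValueError("bin edges must cover [0, 1]")
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")
    counts, _ = np.histogram(scores, bins=edges)
    return 100.0 * counts / len(scores)
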