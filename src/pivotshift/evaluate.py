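"""Diagnostic-accuracy statistics: confusion counts, chi-square, MWU, ROC.

Per-class bookkeeping follows the one-vs-rest convention: for class k,
TP = #(true=k, pred=k), FP = #(true!=k, pred=k), FN = #(true=k, pred!=k).

The ``accuracy`` reported per class by :func:`paper_metrics` is
TP / (TP + FP + FN) — the critical success index (threat score), not the
standard accuracy with true negatives in the denominator.  It is exposed
under the name ``accuracy_paper`` because published per-class "accuracy"
columns for this instrument are arithmetically this quantity; standard
multiclass accuracy is available separately via
:func:`multiclass_accuracy`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "confusion_counts",
    "paper_metrics",
    "f1_from_pr",
    "multiclass_accuracy",
    "chi_square_independence",
    "chi_square_critical",
    "mann_whitney_u",
    "roc_auc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class TP/FP/FN triples keyed by class label."""

    counts: dict

    def __getitem__(self, k):
        return self.counts[k]

    @property
    def total(self) -> tuple[int, int, int]:
        """Aggregate (TP, FP, FN) summed over classes."""
        tp = sum(c[0] for c in self.counts.values())
        fp = sum(c[1] for c in self.counts.values())
        fn = sum(c[2] for c in self.counts.values())
        return tp, fp, fn


@dataclass(frozen=True)
class MetricSet:
    """The four printed metrics, as percentages in [0, 100]."""

    accuracy_paper: float
    precision: float
    recall: float
    f1: float


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """One-vs-rest TP/FP/FN per observed class label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    out = {}
    for k in np.unique(np.concatenate([y_true, y_pred])):
        tp = int(np.sum((y_true == k) & (y_pred == k)))
        fp = int(np.sum((y_true != k) & (y_pred == k)))
        fn = int(np.sum((y_true == k) & (y_pred != k)))
        out[k.item()] = (tp, fp, fn)
    return ConfusionCounts(out)


def paper_metrics(tp: int, fp: int, fn: int) -> MetricSet:
    """Metrics from one (TP, FP, FN) triple, as percentages.

    precision = TP/(TP+FP); recall = TP/(TP+FN); F1 = 2TP/(2TP+FP+FN);
    accuracy_paper = TP/(TP+FP+FN), the critical success index.
    """
    if tp + fp + fn <= 0:
        raise ValueError("all counts zero: metrics undefined")
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0 or tp + fn == 0:
        raise ValueError("zero denominator: precision/recall undefined")
    return MetricSet(
        accuracy_paper=100.0 * tp / (tp + fp + fn),
        precision=100.0 * tp / (tp + fp),
        recall=100.0 * tp / (tp + fn),
        f1=100.0 * 2 * tp / (2 * tp + fp + fn),
    )


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (percent in, percent out)."""
    if precision + recall == 0:
        raise ValueError("precision + recall is zero")
    if not (0 < precision <= 100 and 0 < recall <= 100):
        raise ValueError("precision and recall must be in (0, 100]")
    return 2 * precision * recall / (precision + recall)


def multiclass_accuracy(y_true, y_pred) -> float:
    """Standard fraction-correct accuracy (0..1)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    return float(np.mean(y_true == y_pred))


def chi_square_independence(table) -> dict:
    """Pearson chi-square test of independence on a contingency table.

    Statistic = sum (O-E)^2/E with E = row_total * col_total / N;
    df = (R-1)(C-1); upper-tail p; no continuity correction.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be 2-D")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero row/column margin: expected counts undefined")
    stat, p, df, _ = _stats.chi2_contingency(table, correction=False)
    return {"statistic": float(stat), "df": int(df), "p": float(p)}


def chi_square_critical(alpha: float, df: int) -> float:
    """Upper-alpha critical value of the chi-square distribution."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(_stats.chi2.ppf(1 - alpha, df))


def mann_whitney_u(a, b, alternative: str = "two_sided") -> dict:
    """Mann-Whitney U test with midranks for ties.

    Exact p by enumeration of rank assignments when n_a + n_b <= 16 and no
    ties are present; otherwise the normal approximation with tie
    correction and continuity correction.  The ``method`` field records
    which path was taken.  ``U`` is the statistic of the first sample
    (U_a + U_b = n_a * n_b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}.get(alternative)
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    no_ties = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
    method = "exact" if (a.size + b.size <= 16 and no_ties) else "asymptotic"
    res = _stats.mannwhitneyu(
        a, b, alternative=alt, method=method, use_continuity=True
    )
    return {"U": float(res.statistic), "p": float(res.pvalue), "method": method}


def roc_auc(scores, labels) -> dict:
    """ROC curve and area under it for a binary ground truth.

    The curve sweeps thresholds over the unique scores; the AUC is the
    trapezoidal area, which equals the pair-counting estimator (ties count
    one half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("labels must contain exactly two values")
    y = (labels == uniq.max()).astype(int)
    fpr, tpr, thresholds = _sk_roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return {"fpr": fpr, "tpr": tpr, "thresholds": thresholds, "auc": auc}
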