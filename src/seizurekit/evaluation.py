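"""Confusion-matrix metrics, ROC-AUC and fold-wise model comparison.

Seven metrics are reported on the percent scale, computed directly from the
four binary confusion-matrix cells:

    SEN = TP/(TP+FN)·100              sensitivity (recall)
    SPF = TN/(TN+FP)·100              specificity
    ACC = (TP+TN)/total·100           accuracy
    PPV = TP/(TP+FP)·100              positive predictive value (precision)
    NPV = TN/(TN+FN)·100              negative predictive value
    MCC = (TP·TN−FN·FP)/√((TP+FN)(TP+FP)(TN+FN)(TN+FP))·100
    F1  = 2·TP/(2·TP+FN+FP)·100

A zero denominator makes the metric *undefined*: it is reported as NaN with
an explicit flag and excluded from macro averages (with a warning), never
silently zero.  Multi-class matrices are scored one-vs-rest per class and
macro-averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "BinaryCounts",
    "MetricsReport",
    "ComparisonResult",
    "confusion_counts",
    "compute_metrics",
    "one_vs_rest_metrics",
    "roc_auc",
    "compare_models",
]

METRIC_NAMES = ("SEN", "SPF", "ACC", "PPV", "NPV", "MCC", "F1")


@dataclass(frozen=True)
class BinaryCounts:
    """The four cells of a binary confusion matrix."""

    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP


@dataclass
class MetricsReport:
    """Percent-scale metric values with undefined-ratio flags.

    ``values`` maps each of the seven metric names to a percent value (NaN
    when flagged undefined); ``per_class`` carries the one-vs-rest
    breakdown for multi-class inputs (``values`` is then the macro mean
    over classes with defined values).
    """

    values: dict[str, float]
    undefined: frozenset[str] = frozenset()
    counts: BinaryCounts | None = None
    per_class: dict[int, "MetricsReport"] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    """k x k confusion matrix, rows true class, columns predicted class."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _binary_report(c: BinaryCounts) -> MetricsReport:
    TP, FN, TN, FP = c.TP, c.FN, c.TN, c.FP
    values: dict[str, float] = {}
    undefined: set[str] = set()

    def ratio(name: str, num: float, den: float) -> None:
        if den == 0:
            values[name] = float("nan")
            undefined.add(name)
        else:
            values[name] = 100.0 * num / den

    ratio("SEN", TP, TP + FN)
    ratio("SPF", TN, TN + FP)
    ratio("ACC", TP + TN, c.total)
    ratio("PPV", TP, TP + FP)
    ratio("NPV", TN, TN + FN)
    mcc_den = np.sqrt(
        float(TP + FN) * float(TP + FP) * float(TN + FN) * float(TN + FP)
    )
    if mcc_den == 0:
        values["MCC"] = float("nan")
        undefined.add("MCC")
    else:
        values["MCC"] = 100.0 * (TP * TN - FN * FP) / mcc_den
    ratio("F1", 2 * TP, 2 * TP + FN + FP)
    return MetricsReport(values=values, undefined=frozenset(undefined), counts=c)


def compute_metrics(cm: BinaryCounts | np.ndarray) -> MetricsReport:
    """Score a confusion matrix.

    Accepts :class:`BinaryCounts`, a 2x2 matrix (rows true, columns
    predicted, class 1 positive), or a k x k matrix (scored one-vs-rest and
    macro-averaged).
    """
    if isinstance(cm, BinaryCounts):
        return _binary_report(cm)
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.shape[0] < 2:
        raise ValueError(f"expected a square confusion matrix, got shape {cm.shape}")
    if cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    if np.any(cm < 0):
        raise ValueError("confusion counts must be non-negative")
    if cm.shape[0] == 2:
        return _binary_report(
            BinaryCounts(TP=int(cm[1, 1]), FN=int(cm[1, 0]), TN=int(cm[0, 0]), FP=int(cm[0, 1]))
        )
    return one_vs_rest_metrics(cm)


def one_vs_rest_metrics(cm: np.ndarray) -> MetricsReport:
    """Per-class one-vs-rest reports plus their unweighted macro mean.

    Class ``c``'s binary matrix collapses row/column ``c`` against the
    rest.  Metrics undefined for some class are excluded from that
    metric's macro average with a warning.
    """
    cm = np.asarray(cm)
    k = cm.shape[0]
    total = int(cm.sum())
    per_class: dict[int, MetricsReport] = {}
    for c in range(k):
        TP = int(cm[c, c])
        FN = int(cm[c].sum() - cm[c, c])
        FP = int(cm[:, c].sum() - cm[c, c])
        TN = total - TP - FN - FP
        per_class[c] = _binary_report(BinaryCounts(TP=TP, FN=FN, TN=TN, FP=FP))

    macro: dict[str, float] = {}
    undefined: set[str] = set()
    for name in METRIC_NAMES:
        vals = [r.values[name] for r in per_class.values() if name not in r.undefined]
        if len(vals) < k:
            warnings.warn(
                f"{name}: undefined for {k - len(vals)}/{k} classes; "
                "macro average over the defined classes only",
                stacklevel=2,
            )
        if vals:
            macro[name] = float(np.mean(vals))
        else:
            macro[name] = float("nan")
            undefined.add(name)
    return MetricsReport(
        values=macro, undefined=frozenset(undefined), per_class=per_class
    )


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation.

    Midranks handle tied scores, so identical scores for every sample give
    exactly 0.5.  Raises if only one class is present.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores lengths differ")
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = stats.rankdata(scores)  # midranks for ties
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class ComparisonResult:
    """Fold-paired comparison of two models' accuracy vectors."""

    t_pvalue: float
    wilcoxon_pvalue: float
    cohens_d: float
    mean_difference: float
    degenerate: bool  # zero variance of the paired differences


def compare_models(acc_a: np.ndarray, acc_b: np.ndarray) -> ComparisonResult:
    """Paired t-test, Wilcoxon signed-rank test and Cohen's d on fold-wise
    metric vectors (paired by fold).

    Cohen's d for paired designs is mean(diff)/sd(diff) (sample SD).  When
    every paired difference is identical the tests are degenerate: flagged,
    with the all-zero case reported as p = 1 by convention.
    """
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"fold vectors must pair up: {a.shape} vs {b.shape}")
    if a.ndim != 1 or len(a) < 5:
        raise ValueError("need >= 5 paired folds")
    diff = a - b
    sd = diff.std(ddof=1)
    mean_diff = float(diff.mean())
    if sd == 0.0:
        if np.allclose(diff, 0.0):
            return ComparisonResult(
                t_pvalue=float("nan"),
                wilcoxon_pvalue=1.0,
                cohens_d=float("nan"),
                mean_difference=mean_diff,
                degenerate=True,
            )
        return ComparisonResult(
            t_pvalue=float("nan"),
            wilcoxon_pvalue=float(
                stats.wilcoxon(a, b, zero_method="wilcox").pvalue
            ),
            cohens_d=float(np.sign(mean_diff) * np.inf),
            mean_difference=mean_diff,
            degenerate=True,
        )
    t_p = float(stats.ttest_rel(a, b).pvalue)
    if np.allclose(diff, 0.0):
        w_p = 1.0
    else:
        w_p = float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)
    return ComparisonResult(
        t_pvalue=t_p,
        wilcoxon_pvalue=w_p,
        cohens_d=float(mean_diff / sd),
        mean_difference=mean_diff,
        degenerate=False,
    )
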