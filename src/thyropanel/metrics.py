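"""Diagnostic performance reporting.

Positive class is *malignant* throughout: sensitivity is the malignant
detection rate.  Binomial confidence intervals use the Wilson score
interval (uncorrected variant — the continuity-corrected form is not
used).  PPV/NPV can be re-projected to an assumed prevalence via Bayes'
rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionCounts",
    "MetricCI",
    "MetricsReport",
    "confusion",
    "wilson_interval",
    "diagnostic_metrics",
    "prevalence_adjusted",
    "roc_auc",
    "roc_points",
    "stratified_accuracy",
    "FIG3H_RELABEL",
]

#: Histotype relabeling used for stratified reporting: Hürthle-cell tumors
#: are counted with their follicular counterparts.
FIG3H_RELABEL = {"HCA": "FA", "HCC": "FTC"}


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with malignant as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.total


@dataclass(frozen=True)
class MetricCI:
    point: float
    lower: float
    upper: float


@dataclass
class MetricsReport:
    counts: ConfusionCounts
    sensitivity: Optional[MetricCI]
    specificity: Optional[MetricCI]
    ppv: Optional[MetricCI]
    npv: Optional[MetricCI]
    accuracy: MetricCI
    prevalence: float
    auc: Optional[float] = None

    def to_dict(self) -> dict:
        def unpack(m):
            return None if m is None else {"point": m.point, "lower": m.lower, "upper": m.upper}

        return {
            "counts": {"TP": self.counts.tp, "TN": self.counts.tn, "FP": self.counts.fp, "FN": self.counts.fn},
            "sensitivity": unpack(self.sensitivity),
            "specificity": unpack(self.specificity),
            "PPV": unpack(self.ppv),
            "NPV": unpack(self.npv),
            "accuracy": unpack(self.accuracy),
            "prevalence": self.prevalence,
            "AUC": self.auc,
        }


def confusion(truth, predicted, positive="malignant") -> ConfusionCounts:
    """Tally a 2x2 table; ``positive`` is the malignant-class label value."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    t = truth == positive
    p = predicted == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for ``k`` successes of ``n`` trials."""
    if n <= 0:
        raise ValueError("n must be > 0")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    # the score interval is exactly [0, .] at k = 0 and [., 1] at k = n;
    # snap away float round-off at those boundaries
    lo = 0.0 if k == 0 else float(lo)
    hi = 1.0 if k == n else float(hi)
    return max(lo, 0.0), min(hi, 1.0)


def _metric_ci(k: int, n: int, level: float) -> Optional[MetricCI]:
    if n == 0:
        return None
    lo, hi = wilson_interval(k, n, level)
    return MetricCI(k / n, lo, hi)


def diagnostic_metrics(c: ConfusionCounts, level: float = 0.95) -> MetricsReport:
    """Sensitivity/specificity/PPV/NPV/accuracy with Wilson intervals.

    A metric with a zero denominator is reported as None (undefined), never
    as 0.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    return MetricsReport(
        counts=c,
        sensitivity=_metric_ci(c.tp, c.tp + c.fn, level),
        specificity=_metric_ci(c.tn, c.tn + c.fp, level),
        ppv=_metric_ci(c.tp, c.tp + c.fp, level),
        npv=_metric_ci(c.tn, c.tn + c.fn, level),
        accuracy=_metric_ci(c.tp + c.tn, c.total, level),
        prevalence=c.prevalence,
    )


def prevalence_adjusted(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[Optional[float], Optional[float]]:
    """Re-project (PPV, NPV) to an assumed prevalence via Bayes' rule."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity), ("prevalence", prevalence)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    p = prevalence
    ppv_den = sensitivity * p + (1 - specificity) * (1 - p)
    npv_den = specificity * (1 - p) + (1 - sensitivity) * p
    ppv = sensitivity * p / ppv_den if ppv_den > 0 else None
    npv = specificity * (1 - p) / npv_den if npv_den > 0 else None
    return ppv, npv


def roc_auc(scores, truth, positive="malignant") -> float:
    """AUC by the rank (Mann-Whitney) formulation with midrank tie handling.

    ``scores`` must be malignancy scores: higher means more likely
    malignant.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    pos = truth == positive
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(scores, truth, positive="malignant") -> pd.DataFrame:
    """ROC curve points (FPR, TPR) at every distinct score threshold."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    pos = truth == positive
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = pos[order]
    tps = np.cumsum(sorted_pos)
    fps = np.cumsum(~sorted_pos)
    # keep the last index of each tied-score run
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], len(sorted_scores) - 1]
    rows = [(np.inf, 0.0, 0.0)] + [
        (sorted_scores[i], fps[i] / n_neg, tps[i] / n_pos) for i in distinct
    ]
    return pd.DataFrame(rows, columns=["threshold", "fpr", "tpr"])


def stratified_accuracy(
    truth,
    predicted,
    annotation: pd.DataFrame,
    key: str,
    relabel: Optional[dict] = None,
) -> pd.DataFrame:
    """Per-stratum correct/total table on an annotation column.

    ``relabel`` optionally merges strata before counting (e.g. the
    Hürthle-cell convention :data:`FIG3H_RELABEL`).
    """
    if key not in annotation.columns:
        raise KeyError(f"annotation has no column {key!r}")
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if len(truth) != len(annotation) or len(predicted) != len(annotation):
        raise ValueError("labels and annotation must align")
    strata = annotation[key].astype(str)
    if relabel:
        strata = strata.replace(relabel)
    correct = truth == predicted
    rows = []
    for name in sorted(strata.unique()):
        mask = (strata == name).to_numpy()
        n = int(mask.sum())
        k = int(correct[mask].sum())
        rows.append({"stratum": name, "correct": k, "total": n, "accuracy": k / n})
    return pd.DataFrame(rows).set_index("stratum")
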