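"""Classification metrics and simple two-group statistics.

ROC/AUC, Youden best-point thresholding, confusion summaries (including
MCC), and the Welch-t / chi-square comparison tables used to contrast
patient groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RocCurve",
    "ConfusionSummary",
    "roc_curve",
    "roc_auc",
    "youden_best_point",
    "confusion_metrics",
    "two_group_tests",
]


def _validate_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if not np.isin(uniq, [0, 1]).all():
        raise ValueError(f"labels must be binary 0/1, got values {uniq}")
    if uniq.size < 2:
        raise ValueError("labels contain a single class; need both 0 and 1")
    return labels.astype(int)


@dataclass(frozen=True)
class RocCurve:
    """ROC curve under the 'higher score => predicted positive' orientation.

    ``thresholds`` are ascending candidate cut points (midpoints between
    consecutive distinct scores plus -inf/+inf); a sample is called
    positive when its score exceeds the threshold.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    def __post_init__(self) -> None:
        if not (
            len(self.thresholds) == len(self.sensitivity) == len(self.specificity)
        ):
            raise ValueError("ROC arrays must have equal length")


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney probability that a random positive outscores
    a random negative, ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    labels = _validate_binary(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve(scores, labels) -> RocCurve:
    """Build the ROC curve over midpoint candidate thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = _validate_binary(labels)
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    pos = labels == 1
    n_pos, n_neg = pos.sum(), (~pos).sum()
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = scores > t
        sens[i] = (pred & pos).sum() / n_pos
        spec[i] = (~pred & ~pos).sum() / n_neg
    return RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec)


def youden_best_point(roc: RocCurve) -> tuple[float, float, float]:
    """Threshold maximising J = sensitivity + specificity - 1.

    Ties broken toward higher specificity, then lower threshold.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    best = best[roc.specificity[best] >= roc.specificity[best].max() - 1e-12]
    idx = best[np.argmin(roc.thresholds[best])]
    return (
        float(roc.thresholds[idx]),
        float(roc.sensitivity[idx]),
        float(roc.specificity[idx]),
    )


def confusion_metrics(predicted, labels) -> ConfusionSummary:
    predicted = np.asarray(predicted).astype(int)
    labels = np.asarray(labels).astype(int)
    if predicted.shape != labels.shape:
        raise ValueError("predicted and labels must have the same length")
    tp = int(((predicted == 1) & (labels == 1)).sum())
    fp = int(((predicted == 1) & (labels == 0)).sum())
    tn = int(((predicted == 0) & (labels == 0)).sum())
    fn = int(((predicted == 0) & (labels == 1)).sum())
    n = tp + fp + tn + fn
    acc = (tp + tn) / n if n else float("nan")
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
    return ConfusionSummary(tp, fp, tn, fn, acc, sens, spec, float(mcc))


_CONTINUOUS = ["age", "disease_duration", "baseline_das", "delta_das"]
_CATEGORICAL = ["gender", "response"]


def two_group_tests(
    clinical,
    grouping,
    *,
    welch: bool = True,
    yates: bool = False,
) -> pd.DataFrame:
    """Per-variable comparison of two patient groups.

    ``clinical`` may be a ClinicalTable or its DataFrame.  Continuous
    variables get a two-sample t-test (Welch by default), categorical
    variables a chi-square test on the 2x2 table (no continuity
    correction by default).  Returns a table with group means/counts
    and p-values; untestable variables get NaN.
    """
    if hasattr(clinical, "frame"):
        clinical = clinical.frame
    grouping = np.asarray(grouping).astype(int)
    if len(grouping) != len(clinical):
        raise ValueError("grouping length must match clinical table")
    g1 = clinical.loc[grouping == 1]
    g0 = clinical.loc[grouping == 0]
    rows = []
    for var in clinical.columns:
        if var == "patient_id":
            continue
        a, b = g1[var].dropna(), g0[var].dropna()
        if var in _CATEGORICAL:
            table = np.array(
                [
                    [(a == 1).sum(), (a == 0).sum()],
                    [(b == 1).sum(), (b == 0).sum()],
                ]
            )
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                p = np.nan
            else:
                p = stats.chi2_contingency(table, correction=yates)[1]
            rows.append(
                {
                    "variable": var,
                    "group1": float(a.mean()),
                    "group0": float(b.mean()),
                    "test": "chi-square",
                    "p_value": p,
                }
            )
        elif var in _CONTINUOUS or pd.api.types.is_numeric_dtype(clinical[var]):
            if len(a) < 2 or len(b) < 2:
                p = np.nan
            else:
                p = stats.ttest_ind(a, b, equal_var=not welch).pvalue
            rows.append(
                {
                    "variable": var,
                    "group1": float(a.mean()) if len(a) else np.nan,
                    "group0": float(b.mean()) if len(b) else np.nan,
                    "test": "t-test",
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows).set_index("variable")
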