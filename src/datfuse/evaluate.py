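"""Performance metrics, permutation significance, and ROC analysis.

Metrics use the patient class as positive: accuracy, sensitivity (true
positive rate), specificity (true negative rate) and precision are the
standard confusion-matrix ratios. A metric whose denominator is zero is
reported as NaN and listed in ``MetricSet.undefined`` — never silently 0.

The permutation test reruns the *entire* classification pipeline (including
any inner-loop weight estimation) under randomly rearranged diagnostic
labels, building an empirical null for the reference accuracy. The reported
p-value uses the at-least-as-extreme correction

    p = (1 + #{permuted accuracy ≥ reference}) / (n_perm + 1),

so p is never exactly zero and is valid for finite permutation counts.
A complementary one-sample t-test compares the permuted-accuracy mean
against the reference accuracy (two-sided, with a 95% CI of the permuted
mean); its statistic is reported signed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "PermutationRun",
    "OneSampleT",
    "RocCurve",
    "confusion",
    "metrics",
    "permutation_test",
    "one_sample_t",
    "roc_curve",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Accuracy / sensitivity / specificity / precision; NaN where undefined."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
        }


@dataclass(frozen=True)
class PermutationRun:
    reference: float
    permuted: np.ndarray
    n_perm: int
    pvalue: float


@dataclass(frozen=True)
class OneSampleT:
    statistic: float
    pvalue: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def confusion(
    predictions: Sequence[str],
    labels: Sequence[str],
    positive_class: str = "PD",
) -> ConfusionCounts:
    """Confusion counts with the stated positive (patient) class."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0:
        raise ValueError("no predictions to score")
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels differ in length")
    seen = set(np.unique(predictions)) | set(np.unique(labels))
    if len(seen - {positive_class}) > 1:
        raise ValueError(
            f"more than two classes seen: {sorted(seen)}; binary scoring only"
        )
    pos_pred = predictions == positive_class
    pos_true = labels == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos_pred & pos_true)),
        tn=int(np.sum(~pos_pred & ~pos_true)),
        fp=int(np.sum(pos_pred & ~pos_true)),
        fn=int(np.sum(~pos_pred & pos_true)),
    )


def _ratio(num: int, den: int, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return float("nan")
    return num / den


def metrics(counts: ConfusionCounts) -> MetricSet:
    """The four standard ratios from confusion counts."""
    if counts.total == 0:
        raise ValueError("no evaluated subjects")
    undef: set[str] = set()
    return MetricSet(
        accuracy=(counts.tp + counts.tn) / counts.total,
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn, "sensitivity", undef),
        specificity=_ratio(counts.tn, counts.tn + counts.fp, "specificity", undef),
        precision=_ratio(counts.tp, counts.tp + counts.fp, "precision", undef),
        undefined=frozenset(undef),
    )


def permutation_test(
    pipeline: Callable[[pd.Series], float],
    labels: pd.Series,
    n_perm: int,
    seed: int,
) -> PermutationRun:
    """Label-permutation null for a classification pipeline.

    ``pipeline`` maps a label Series (same index as ``labels``) to an
    accuracy; it must be deterministic given the labels, otherwise the
    permutation null is invalid. The reference accuracy uses the original
    labels; each of the ``n_perm`` reruns uses an independent uniform
    rearrangement of them.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    reference = float(pipeline(labels))
    check = float(pipeline(labels))
    if check != reference:
        raise ValueError(
            "pipeline is not deterministic given the labels; permutation "
            "null invalid"
        )
    rng = np.random.default_rng(seed)
    values = labels.to_numpy()
    permuted = np.zeros(n_perm)
    for i in range(n_perm):
        shuffled = pd.Series(rng.permutation(values), index=labels.index)
        permuted[i] = float(pipeline(shuffled))
    pvalue = (1.0 + np.sum(permuted >= reference)) / (n_perm + 1.0)
    return PermutationRun(reference, permuted, n_perm, float(pvalue))


def one_sample_t(permuted: Sequence[float], reference: float) -> OneSampleT:
    """Two-sided one-sample t of the permuted-accuracy mean vs the reference."""
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size < 2:
        raise ValueError("need at least 2 permuted accuracies")
    if permuted.std(ddof=1) == 0:
        raise ValueError("permuted accuracies have zero variance")
    res = stats.ttest_1samp(permuted, popmean=reference)
    ci = res.confidence_interval(0.95)
    return OneSampleT(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
    )


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[str],
    positive_class: str = "PD",
) -> RocCurve:
    """TPR/FPR sweep over score thresholds with trapezoidal AUC.

    Tied scores cross their threshold simultaneously (one ROC vertex per
    distinct score), so AUC equals the pairwise ranking probability with the
    half-credit-for-ties convention.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    pos = labels == positive_class
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = _sk_roc_curve(pos.astype(int), scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)
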