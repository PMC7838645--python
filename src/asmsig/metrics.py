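"""Multiclass Matthews correlation coefficient and accuracy measures.

The multiclass MCC follows Gorodkin's covariance formulation: with X the
samples x classes 0-1 indicator matrix of the predictions and Y the same
for the actual labels,

    MCC = cov(X, Y) / sqrt(cov(X, X) * cov(Y, Y))

where cov(A, B) is the mean over classes of the per-column sample
covariances.  The value lies in [-1, +1]; +1 is perfect prediction.  When
either denominator covariance is zero (a degenerate single-class vector)
the coefficient is defined as 0, which keeps performance curves
well-defined for classifiers that collapse onto one class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class PerformanceRecord:
    """Per-class accuracy, overall accuracy (ACC) and multiclass MCC.

    ``per_class_accuracy`` holds the fraction of correctly predicted
    samples within each *actual* class; classes absent from the actual
    labels are omitted.  ACC equals the class-size-weighted mean of the
    per-class accuracies.
    """

    per_class_accuracy: Mapping[str, float]
    acc: float
    mcc: float

    def as_dict(self) -> dict:
        return {
            "per_class_accuracy": dict(self.per_class_accuracy),
            "acc": self.acc,
            "mcc": self.mcc,
        }


def _check_labels(
    actual: Sequence, predicted: Sequence, class_order: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list]:
    actual = np.asarray(actual, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if actual.size == 0:
        raise ValueError("empty label sequences")
    if actual.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: {actual.size} actual vs {predicted.size} predicted"
        )
    classes = list(class_order)
    if len(set(classes)) != len(classes):
        raise ValueError("class_order contains duplicates")
    known = set(classes)
    for name, arr in (("actual", actual), ("predicted", predicted)):
        unknown = [x for x in np.unique(arr) if x not in known]
        if unknown:
            raise ValueError(f"unknown label {unknown[0]!r} in {name} labels")
    return actual, predicted, classes


def indicator_matrix(labels: Sequence, class_order: Sequence[str]) -> np.ndarray:
    """Samples x classes 0-1 matrix; each row sums to exactly 1."""
    labels = np.asarray(labels, dtype=object)
    idx = {c: j for j, c in enumerate(class_order)}
    out = np.zeros((labels.size, len(class_order)))
    for i, lab in enumerate(labels):
        out[i, idx[lab]] = 1.0
    return out


def multiclass_mcc(
    actual: Sequence,
    predicted: Sequence,
    class_order: Sequence[str] | None = None,
) -> float:
    """Gorodkin multiclass MCC of a prediction against the truth."""
    if class_order is None:
        class_order = sorted(set(actual) | set(predicted))
    actual, predicted, classes = _check_labels(actual, predicted, class_order)
    Y = indicator_matrix(actual, classes)
    X = indicator_matrix(predicted, classes)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    # mean over classes of per-column covariances; the 1/(nK) factors cancel
    cov_xy = float((Xc * Yc).sum())
    cov_xx = float((Xc * Xc).sum())
    cov_yy = float((Yc * Yc).sum())
    if cov_xx == 0.0 or cov_yy == 0.0:
        return 0.0
    return cov_xy / np.sqrt(cov_xx * cov_yy)


def performance_record(
    actual: Sequence,
    predicted: Sequence,
    class_order: Sequence[str] | None = None,
) -> PerformanceRecord:
    """Per-class accuracies, ACC and MCC of one pooled prediction."""
    if class_order is None:
        class_order = sorted(set(actual) | set(predicted))
    actual, predicted, classes = _check_labels(actual, predicted, class_order)
    correct = actual == predicted
    per_class: dict[str, float] = {}
    for c in classes:
        mask = actual == c
        if mask.any():
            per_class[c] = float(correct[mask].mean())
    return PerformanceRecord(
        per_class_accuracy=per_class,
        acc=float(correct.mean()),
        mcc=multiclass_mcc(actual, predicted, classes),
    )
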