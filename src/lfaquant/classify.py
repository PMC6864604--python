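"""Multiclass linear SVM on the regression-approximated quantity.

The classifier input is the scalar x-hat = (T/C - b) / m, the calibrated
log-quantity of a strip. A soft-margin linear SVM is trained one-vs-one over
the quantity classes; since the feature is scalar and the classes ordered,
each pairwise decision is a single boundary point and prediction reduces to
majority voting over boundary crossings. For large C on separable data each
boundary converges to the midpoint of the closest opposing pair (the 1-D
max-margin separator).

Evaluation uses stratified k-fold cross-validation with out-of-fold
predictions accumulated into one confusion matrix; overall accuracy is
100 x trace / total, which aggregates the per-class TP/TN/FP/FN counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = ["ClassifierModel", "ConfusionMatrix", "train_svm", "predict", "cross_validate", "accuracy"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix; rows = actual class, columns = predicted class.

    ``labels`` lists the class quantities in the row/column order used
    (descending quantity, the order assay tables are printed in).
    """

    labels: Tuple[float, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        k = len(self.labels)
        if counts.shape != (k, k):
            raise ValueError(f"counts shape {counts.shape} does not match {k} labels")
        if (counts < 0).any():
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return int(np.asarray(self.counts).sum())

    @property
    def diagonal(self) -> int:
        return int(np.trace(np.asarray(self.counts)))

    def to_dict(self) -> dict:
        return {
            "labels_fg": list(self.labels),
            "counts": np.asarray(self.counts).astype(int).tolist(),
            "accuracy_percent": accuracy(self),
        }


@dataclass
class ClassifierModel:
    """A trained one-vs-one linear SVM over ordered quantity classes."""

    svc: SVC
    classes: Tuple[float, ...] = field(default_factory=tuple)
    C: float = 1.0

    def pairwise_boundaries(self) -> Dict[Tuple[float, float], float]:
        """Decision-boundary feature value per class pair (w x + b = 0).

        Keys are (lower, higher) quantity pairs in the SVC's one-vs-one order.
        """
        boundaries: Dict[Tuple[float, float], float] = {}
        coefs = self.svc.coef_
        intercepts = self.svc.intercept_
        classes = self.svc.classes_
        idx = 0
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                w = float(coefs[idx, 0])
                b = float(intercepts[idx])
                boundaries[(float(classes[i]), float(classes[j]))] = (
                    -b / w if w != 0 else float("nan")
                )
                idx += 1
        return boundaries


def train_svm(
    features: Sequence[float], labels: Sequence[float], C: float = 1.0
) -> ClassifierModel:
    """Fit a one-vs-one soft-margin linear SVM on a scalar feature.

    Deterministic given the data and C. Requires at least two classes.
    """
    X = np.asarray(features, dtype=np.float64).reshape(-1, 1)
    y = np.asarray(labels, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 classes to train a classifier")
    svc = SVC(kernel="linear", C=C, decision_function_shape="ovo")
    svc.fit(X, y)
    return ClassifierModel(svc=svc, classes=tuple(float(c) for c in svc.classes_), C=C)


def predict(model: ClassifierModel, features: Sequence[float]) -> np.ndarray:
    """Predict class labels by one-vs-one majority vote.

    Vote ties are broken by the larger aggregate decision margin (the SVC's
    built-in tie resolution), then by class order.
    """
    X = np.asarray(features, dtype=np.float64).reshape(-1, 1)
    return model.svc.predict(X)


def cross_validate(
    features: Sequence[float],
    labels: Sequence[float],
    k: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> ConfusionMatrix:
    """Stratified k-fold CV; out-of-fold predictions pooled into one matrix."""
    if k < 2:
        raise ValueError(f"need k >= 2 folds, got {k}")
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_true: List[float] = []
    y_pred: List[float] = []
    for train_idx, test_idx in skf.split(X.reshape(-1, 1), y):
        model = train_svm(X[train_idx], y[train_idx], C=C)
        y_true.extend(y[test_idx])
        y_pred.extend(predict(model, X[test_idx]))
    return confusion(y_true, y_pred, classes=np.unique(y))


def confusion(
    y_true: Sequence[float], y_pred: Sequence[float], classes: Sequence[float]
) -> ConfusionMatrix:
    """Confusion matrix with classes ordered by descending quantity."""
    order = sorted((float(c) for c in classes), reverse=True)
    counts = _sk_confusion(y_true, y_pred, labels=order)
    return ConfusionMatrix(labels=tuple(order), counts=counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy in percent: 100 x on-diagonal / total predictions."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * cm.diagonal / cm.total
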