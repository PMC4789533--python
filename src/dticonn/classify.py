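"""Leave-one-out linear SVM classification of subjects from edge features.

Each of the n subjects is held out in turn; the remaining n - 1 train a
linear maximum-margin classifier (hinge loss, regularization C).  Features
are standardized with the training fold's mean and standard deviation, so
no information from the held-out subject leaks into the scaling.  The
aggregated out-of-fold predictions yield confusion counts and the usual
percent metrics: sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/n, each reported x100 rounded to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

__all__ = ["FeatureTable", "ClassifierReport", "loocv_linear_svm", "confusion_metrics"]


@dataclass
class FeatureTable:
    """Subject x feature matrix with binary group labels."""

    features: np.ndarray  # (n_subjects, n_features)
    labels: np.ndarray  # (n_subjects,)
    positive_class: str
    feature_names: list[str] | None = None
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        if X.ndim != 2:
            raise ValueError("features must be 2-D (subjects x features)")
        if np.any(~np.isfinite(X)):
            raise ValueError("features must not contain missing/non-finite values")
        y = np.asarray(self.labels)
        if y.shape[0] != X.shape[0]:
            raise ValueError("labels length must match subject count")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("labels must be binary")
        if str(self.positive_class) not in {str(c) for c in classes}:
            raise ValueError("positive_class must be one of the labels")
        counts = [(y == c).sum() for c in classes]
        if min(counts) < 2:
            raise ValueError("each class needs at least 2 subjects")
        self.features = X
        self.labels = y


@dataclass
class ClassifierReport:
    """LOOCV outcome: per-fold predictions, confusion counts, percent metrics."""

    predictions: np.ndarray
    truth: np.ndarray
    positive_class: str
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    accuracy: float
    settings: dict = field(default_factory=dict)

    @property
    def n_folds(self) -> int:
        return len(self.predictions)


def confusion_metrics(predictions, truth, positive_class) -> tuple[float, float, float]:
    """(sensitivity %, specificity %, accuracy %), rounded to 2 decimals."""
    pred = np.asarray(predictions)
    y = np.asarray(truth)
    if pred.shape != y.shape:
        raise ValueError("predictions and truth must have equal length")
    classes = set(np.unique(y).tolist())
    if len(classes) != 2:
        raise ValueError("truth must contain exactly two classes")
    if positive_class not in classes:
        raise ValueError("positive_class absent from truth")
    pos = y == positive_class
    tp = int(np.sum(pos & (pred == positive_class)))
    fn = int(np.sum(pos & (pred != positive_class)))
    tn = int(np.sum(~pos & (pred != positive_class)))
    fp = int(np.sum(~pos & (pred == positive_class)))
    sens = round(100.0 * tp / (tp + fn), 2)
    spec = round(100.0 * tn / (tn + fp), 2)
    acc = round(100.0 * (tp + tn) / len(y), 2)
    return sens, spec, acc


def _confusion_counts(pred, y, positive_class):
    pos = y == positive_class
    return (
        int(np.sum(pos & (pred == positive_class))),
        int(np.sum(pos & (pred != positive_class))),
        int(np.sum(~pos & (pred != positive_class))),
        int(np.sum(~pos & (pred == positive_class))),
    )


def loocv_linear_svm(features: FeatureTable, regularization: float = 1.0) -> ClassifierReport:
    """Leave-one-out cross-validated linear SVM.

    One fold per subject.  Each fold standardizes the features with the
    training subjects' mean/SD (constant training columns are left unscaled)
    and fits ``SVC(kernel="linear", C=regularization)``.  Deterministic for
    fixed inputs.  Raises if any training fold loses a class entirely.
    """
    if regularization <= 0:
        raise ValueError("regularization must be positive")
    X, y = features.features, features.labels
    n = X.shape[0]
    predictions = np.empty(n, dtype=y.dtype)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        y_tr = y[train]
        if np.unique(y_tr).size < 2:
            raise ValueError(f"training fold {i} contains a single class")
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        clf = SVC(kernel="linear", C=regularization)
        clf.fit((X[train] - mu) / sd, y_tr)
        predictions[i] = clf.predict(((X[i] - mu) / sd)[None, :])[0]

    pos = features.positive_class
    tp, fn, tn, fp = _confusion_counts(predictions, y, pos)
    sens, spec, acc = confusion_metrics(predictions, y, pos)
    return ClassifierReport(
        predictions=predictions,
        truth=y.copy(),
        positive_class=pos,
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        settings={
            "kernel": "linear",
            "regularization": regularization,
            "standardization": "per training fold",
            "cv": "leave-one-out",
        },
    )
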