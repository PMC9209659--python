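"""Subtype classification from feature-CpG beta-values.

A soft-margin linear max-margin classifier (one-vs-rest for k > 2)
trained on raw beta features (already bounded in [0, 1], so no
re-scaling). Evaluation is stratified ten-fold cross-validation with
pooled predictions: accuracy, macro recall ("sensitivity"), macro
precision, macro one-vs-rest AUC from decision scores, and the k x k
confusion matrix. An RBF kernel is available via ``kernel="rbf"``.
"""

from __future__ import annotations

import json
import warnings


import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_score, recall_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, LinearSVC

from .types import ClassifierReport, SubtypeAssignment

__all__ = ["SubtypeClassifier", "crossval_report", "fit_and_predict"]


def _as_xy(features: pd.DataFrame, labels: SubtypeAssignment):
    samples = [s for s in features.index if s in labels.of]
    if len(samples) != len(features.index):
        missing = [s for s in features.index if s not in labels.of]
        raise ValueError(f"samples without labels: {missing[:3]}")
    X = features.loc[samples].to_numpy(dtype=float)
    y = labels.labels(samples)
    return X, y, samples


class SubtypeClassifier:
    """Thin wrapper carrying the feature list next to the fitted model."""

    def __init__(self, kernel: str = "linear", C: float = 1.0, seed: int = 0):
        if kernel not in {"linear", "rbf"}:
            raise ValueError(f"kernel must be linear or rbf, got {kernel!r}")
        self.kernel = kernel
        self.C = C
        self.seed = seed
        self.features_: list | None = None
        self.model_ = None

    def _new_model(self):
        if self.kernel == "linear":
            return LinearSVC(C=self.C, random_state=self.seed, max_iter=10_000)
        return SVC(kernel="rbf", C=self.C, random_state=self.seed,
                   decision_function_shape="ovr")

    def fit(self, features: pd.DataFrame, labels: SubtypeAssignment):
        X, y, _ = _as_xy(features, labels)
        self.features_ = list(features.columns)
        self.model_ = self._new_model()
        self.model_.fit(X, y)
        return self

    def _check_features(self, features: pd.DataFrame) -> np.ndarray:
        if self.model_ is None:
            raise ValueError("classifier not trained")
        missing = [f for f in self.features_ if f not in features.columns]
        if missing:
            raise ValueError(f"new samples lack training features: {missing[:5]}")
        return features[self.features_].to_numpy(dtype=float)

    def predict(self, features: pd.DataFrame) -> SubtypeAssignment:
        if len(features.index) == 0:
            return SubtypeAssignment({})
        X = self._check_features(features)
        y = self.model_.predict(X)
        return SubtypeAssignment({s: int(l) for s, l in zip(features.index, y)})

    def decision_scores(self, features: pd.DataFrame) -> np.ndarray:
        X = self._check_features(features)
        scores = self.model_.decision_function(X)
        if scores.ndim == 1:  # binary: expand to two columns
            scores = np.column_stack([-scores, scores])
        return scores

    def save(self, path) -> None:
        """Persist a linear model as a flat JSON file (features, classes,
        per-class weights and intercepts)."""
        if self.kernel != "linear" or self.model_ is None:
            raise ValueError("only fitted linear models can be persisted")
        payload = {
            "kernel": self.kernel, "C": self.C, "seed": self.seed,
            "features": self.features_,
            "classes": [int(c) for c in self.model_.classes_],
            "coef": np.atleast_2d(self.model_.coef_).tolist(),
            "intercept": np.atleast_1d(self.model_.intercept_).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "SubtypeClassifier":
        with open(path) as fh:
            payload = json.load(fh)
        obj = cls(kernel=payload["kernel"], C=payload["C"], seed=payload["seed"])
        model = obj._new_model()
        model.classes_ = np.array(payload["classes"])
        model.coef_ = np.array(payload["coef"])
        model.intercept_ = np.array(payload["intercept"])
        model.n_features_in_ = len(payload["features"])
        obj.model_ = model
        obj.features_ = payload["features"]
        return obj


def _macro_ovr_auc(y: np.ndarray, scores: np.ndarray, classes: np.ndarray) -> float:
    aucs = []
    for i, c in enumerate(classes):
        truth = (y == c).astype(int)
        if truth.min() == truth.max():
            continue
        aucs.append(roc_auc_score(truth, scores[:, i]))
    return float(np.mean(aucs)) if aucs else float("nan")


def crossval_report(features: pd.DataFrame, labels: SubtypeAssignment,
                    folds: int = 10, seed: int = 0, kernel: str = "linear",
                    C: float = 1.0) -> ClassifierReport:
    """Stratified k-fold cross-validation with pooled predictions."""
    X, y, samples = _as_xy(features, labels)
    classes = np.unique(y)
    min_class = int(np.bincount(y)[1:].min()) if classes.size else 0
    if min_class < folds:
        warnings.warn(f"smallest class has {min_class} members; reducing folds "
                      f"from {folds} to {min_class}", stacklevel=2)
        folds = min_class
    if folds < 2:
        raise ValueError("need at least 2 usable folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.zeros_like(y)
    scores = np.zeros((len(y), classes.size))
    for train, test in skf.split(X, y):
        if np.unique(y[train]).size < classes.size:
            raise ValueError("a class is absent from a training fold")
        clf = SubtypeClassifier(kernel=kernel, C=C, seed=seed)
        clf.fit(features.iloc[train], SubtypeAssignment(
            {samples[i]: int(y[i]) for i in train}))
        pred[test] = clf.model_.predict(X[test])
        s = clf.model_.decision_function(X[test])
        if s.ndim == 1:
            s = np.column_stack([-s, s])
        scores[test] = s
    conf = confusion_matrix(y, pred, labels=classes)
    return ClassifierReport(
        confusion=conf,
        accuracy=float(np.trace(conf) / conf.sum()),
        sensitivity=float(recall_score(y, pred, average="macro", zero_division=0)),
        precision=float(precision_score(y, pred, average="macro", zero_division=0)),
        auc=_macro_ovr_auc(y, scores, classes),
        classes=[int(c) for c in classes],
    )


def fit_and_predict(train_features: pd.DataFrame, train_labels: SubtypeAssignment,
                    new_features: pd.DataFrame, kernel: str = "linear",
                    C: float = 1.0, seed: int = 0) -> SubtypeAssignment:
    """Train on the full training cohort and label new samples."""
    clf = SubtypeClassifier(kernel=kernel, C=C, seed=seed)
    clf.fit(train_features, train_labels)
    return clf.predict(new_features)
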