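"""Recursive feature elimination, SVM training, and cross-validated ROC.

Feature ranking uses a linear-kernel SVM (whose weights are defined);
model quality at each retained feature-set size, and the final model, use
an RBF-kernel SVM.  The selected gene set is the one maximizing
stratified k-fold cross-validation accuracy, preferring fewer features on
ties.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "make_labels",
    "FeatureSelectionTrace",
    "rfe_select",
    "DiagnosticModel",
    "train_svm",
    "EvaluationReport",
    "evaluate_cv",
]

SCHEMES = ("benign_vs_malignant", "control_vs_cancer", "early_vs_late")


def make_labels(metadata: pd.DataFrame, scheme: str) -> pd.Series:
    """Binary sample labels under one of the three grouping schemes.

    benign_vs_malignant: stage I/II -> benign, III/IV -> malignant
    (samples without a stage are excluded); control_vs_cancer: control vs
    early+late; early_vs_late: the two cancer phases.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if scheme == "benign_vs_malignant":
        stage = metadata.get("stage")
        staged = metadata[stage.notna()] if stage is not None else metadata.iloc[0:0]
        dropped = len(metadata) - len(staged)
        if dropped:
            logger.info("excluding %d sample(s) without stage information",
                        dropped)
        labels = staged["stage"].map(
            {"I": "benign", "II": "benign",
             "III": "malignant", "IV": "malignant"})
    elif scheme == "control_vs_cancer":
        labels = metadata["phase"].map(
            {"control": "control", "early": "cancer", "late": "cancer"})
    else:
        sub = metadata[metadata["phase"].isin(("early", "late"))]
        labels = sub["phase"]
    labels = labels.dropna()
    counts = labels.value_counts()
    if len(counts) < 2 or counts.min() == 0:
        raise ValueError(f"scheme {scheme!r} yields a single class: "
                         f"{counts.to_dict()}")
    return labels.rename("label")


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, folds: int, seed: int | None,
    C: float = 1.0, gamma="scale",
) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(X, y):
        clf = SVC(kernel="rbf", C=C, gamma=gamma)
        clf.fit(X[train], y[train])
        accs.append(float((clf.predict(X[test]) == y[test]).mean()))
    return float(np.mean(accs))


@dataclasses.dataclass
class FeatureSelectionTrace:
    """The elimination path of recursive feature elimination."""
    elimination_order: list[str]
    accuracy_curve: list[tuple[int, float]]
    selected: list[str]
    all_features: list[str] = dataclasses.field(default_factory=list)

    def top_features(self, k: int) -> list[str]:
        """The k features surviving longest (the RFE ranking's top k)."""
        if not 1 <= k <= len(self.all_features):
            raise ValueError(f"k must be in [1, {len(self.all_features)}]")
        dropped = set(self.elimination_order[:len(self.all_features) - k])
        return [f for f in self.all_features if f not in dropped]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.accuracy_curve,
                            columns=["n_features", "cv_accuracy"])


def rfe_select(
    X: pd.DataFrame,
    y: Sequence[str],
    step: int = 1,
    folds: int = 5,
    seed: int | None = None,
) -> FeatureSelectionTrace:
    """Recursive feature elimination with a CV accuracy curve.

    At each round the current feature set is scored by stratified k-fold
    CV accuracy of an RBF SVM, then a linear-kernel SVM is fit on all
    samples and the ``step`` features with the smallest |weight| are
    dropped.  The selected set is the accuracy-curve argmax (fewest
    features on ties).  Deterministic given the seed.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    y_arr = np.asarray(y)
    classes, counts = np.unique(y_arr, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; "
            f"use fewer than {folds} folds")
    feats = list(X.columns)
    curve: list[tuple[int, float]] = []
    snapshots: list[list[str]] = []
    eliminated: list[str] = []
    while feats:
        acc = _cv_accuracy(X[feats].to_numpy(), y_arr, folds, seed)
        curve.append((len(feats), acc))
        snapshots.append(list(feats))
        if len(feats) == 1:
            break
        lin = SVC(kernel="linear", C=1.0)
        lin.fit(X[feats].to_numpy(), y_arr)
        importance = np.abs(lin.coef_[0])
        order = np.argsort(importance, kind="mergesort")  # stable: ties by column order
        drop = [feats[i] for i in order[:min(step, len(feats) - 1)]]
        eliminated.extend(drop)
        feats = [f for f in feats if f not in drop]
    best = max(range(len(curve)), key=lambda i: (curve[i][1], -curve[i][0]))
    return FeatureSelectionTrace(eliminated, curve, snapshots[best],
                                 list(X.columns))


@dataclasses.dataclass
class DiagnosticModel:
    """A tuned RBF-SVM over a selected gene panel."""
    features: list[str]
    kernel: str
    C: float
    gamma: float | str
    classes: tuple[str, str]
    cv_accuracy: float
    estimator: SVC = dataclasses.field(repr=False)

    def to_dict(self) -> dict:
        return {
            "features": self.features, "kernel": self.kernel,
            "C": self.C, "gamma": self.gamma,
            "classes": list(self.classes), "cv_accuracy": self.cv_accuracy,
        }


def train_svm(
    X: pd.DataFrame,
    y: Sequence[str],
    features: Sequence[str] | None = None,
    grid: Mapping[str, Sequence] | None = None,
    folds: int = 5,
    seed: int | None = None,
) -> DiagnosticModel:
    """Exhaustive grid search over (C, gamma) by stratified CV accuracy.

    Ties break toward smaller C, then smaller gamma (string gammas such as
    "scale" sort before numeric ones).  The winning cell is refit on all
    samples.
    """
    feats = list(features) if features is not None else list(X.columns)
    Xs = X[feats].to_numpy(dtype=float)
    if not np.isfinite(Xs).all():
        raise ValueError("non-finite feature values")
    y_arr = np.asarray(y)
    if grid is None:
        grid = {"C": (0.1, 1.0, 10.0, 100.0),
                "gamma": ("scale", 0.001, 0.01, 0.1)}
    if not grid.get("C") or not grid.get("gamma"):
        raise ValueError("grid must list at least one C and one gamma")

    def _gamma_key(g):  # "scale"/"auto" first, then ascending numeric
        return (0, 0.0) if isinstance(g, str) else (1, float(g))

    cells = itertools.product(sorted(grid["C"]),
                              sorted(grid["gamma"], key=_gamma_key))
    best = None
    for C, gamma in cells:
        acc = _cv_accuracy(Xs, y_arr, folds, seed, C=C, gamma=gamma)
        if best is None or acc > best[0]:
            best = (acc, C, gamma)
    acc, C, gamma = best
    clf = SVC(kernel="rbf", C=C, gamma=gamma)
    clf.fit(Xs, y_arr)
    classes = tuple(clf.classes_)
    return DiagnosticModel(feats, "rbf", float(C), gamma, classes,
                           float(acc), clf)


@dataclasses.dataclass
class EvaluationReport:
    """Per-fold ROC curves and summary accuracy of a cross-validated model."""
    fold_curves: list[tuple[np.ndarray, np.ndarray]]
    fold_aucs: list[float]
    fold_accuracies: list[float]
    auroc: float
    accuracy: float
    folds: int
    seed: int | None


def evaluate_cv(
    X: pd.DataFrame,
    y: Sequence[str],
    features: Sequence[str] | None = None,
    C: float = 1.0,
    gamma="scale",
    folds: int = 5,
    seed: int | None = None,
) -> EvaluationReport:
    """Stratified k-fold evaluation with per-fold ROC from decision scores.

    AUROC is the trapezoidal area of each fold's ROC, averaged across
    folds; accuracy is the mean per-fold accuracy.  Fold assignments are
    reproducible from the seed.
    """
    feats = list(features) if features is not None else list(X.columns)
    Xs = X[feats].to_numpy(dtype=float)
    y_arr = np.asarray(y)
    classes, counts = np.unique(y_arr, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; "
            f"use fewer than {folds} folds")
    pos_label = classes[1]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    curves, aucs, accs = [], [], []
    for train, test in skf.split(Xs, y_arr):
        clf = SVC(kernel="rbf", C=C, gamma=gamma)
        clf.fit(Xs[train], y_arr[train])
        scores = clf.decision_function(Xs[test])
        fpr, tpr, _ = roc_curve(y_arr[test], scores, pos_label=pos_label)
        curves.append((fpr, tpr))
        aucs.append(float(auc(fpr, tpr)))
        accs.append(float((clf.predict(Xs[test]) == y_arr[test]).mean()))
    return EvaluationReport(curves, aucs, accs,
                            float(np.mean(aucs)), float(np.mean(accs)),
                            folds, seed)
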