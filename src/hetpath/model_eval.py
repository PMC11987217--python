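"""Classifier training with grid search, and ROC/F1 evaluation.

The primary classifier is gradient-boosted trees (XGBoost); random forest,
SVM and Gaussian naive Bayes serve as baselines.  Hyperparameters are tuned
by grid search with stratified k-fold cross-validation (3 folds by default)
scored by AUC, ties broken by first-in-grid order.  Evaluation reports AUC
(trapezoidal rule over grouped thresholds, so tied scores receive half
credit) and the F1 score 2TP / (2TP + FN + FP) at a fixed probability
threshold.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import FeatureTable

GBT_PARAM_NAMES = (
    "n_estimators",
    "max_depth",
    "min_child_weight",
    "gamma",
    "colsample_bytree",
    "reg_alpha",
)

#: default grid for the gradient-boosted model; ranges kept small enough
#: for interactive runs and fully overridable through ClassifierSpec.grid
DEFAULT_GBT_GRID: dict[str, list] = {
    "n_estimators": [100, 300, 500],
    "max_depth": [3, 5, 7],
    "min_child_weight": [1, 3],
    "gamma": [0, 0.1],
    "colsample_bytree": [0.8, 1.0],
    "reg_alpha": [0, 0.1],
}


@dataclass
class ClassifierSpec:
    """Which algorithm to fit and how to tune it."""

    algorithm: str = "gbt"          # gbt | rf | svm | nb
    grid: dict[str, list] = field(default_factory=dict)
    cv_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("gbt", "rf", "svm", "nb"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.algorithm == "gbt":
            extra = set(self.grid) - set(GBT_PARAM_NAMES)
            if extra:
                raise ValueError(
                    f"unsupported gbt grid parameters: {sorted(extra)}"
                )


def _make_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "gbt":
        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", **params
        )
    if algorithm == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm == "svm":
        return SVC(probability=True, random_state=seed, **params)
    return GaussianNB(**params)


@dataclass
class FittedModel:
    algorithm: str
    estimator: object
    feature_columns: list[str]
    best_params: dict
    cv_mean_auc: float
    seed: int


def _validate_xy(features: FeatureTable, labels: Sequence[int]):
    X = features.values()
    y = np.asarray(labels, dtype=np.int64)
    if len(X) != len(y):
        raise ValueError("features and labels are not aligned")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes present")
    return X, y


def tune_and_train(
    features: FeatureTable, labels: Sequence[int], spec: ClassifierSpec
) -> FittedModel:
    """Grid search with stratified CV scored by mean AUC, then refit.

    Every grid combination (Cartesian product in key order) is scored by
    the mean validation AUC over ``cv_folds`` stratified folds; the best
    combination — ties going to the first in grid order — is refit on the
    full training set.  Deterministic for a fixed seed.
    """
    X, y = _validate_xy(features, labels)
    grid = spec.grid
    if not grid and spec.algorithm == "gbt":
        grid = DEFAULT_GBT_GRID
    names = list(grid)
    combos = (
        [dict(zip(names, values)) for values in itertools.product(*grid.values())]
        if names
        else [{}]
    )
    best_params, best_auc = combos[0], -np.inf
    if len(combos) > 1 or names:
        skf = StratifiedKFold(
            n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed
        )
        folds = list(skf.split(X, y))
        for params in combos:
            aucs = []
            for tr, va in folds:
                est = _make_estimator(spec.algorithm, params, spec.seed)
                est.fit(X[tr], y[tr])
                scores = est.predict_proba(X[va])[:, 1]
                aucs.append(roc_auc(scores, y[va])[0])
            mean_auc = float(np.mean(aucs))
            if mean_auc > best_auc:
                best_auc, best_params = mean_auc, params
    estimator = _make_estimator(spec.algorithm, best_params, spec.seed)
    estimator.fit(X, y)
    return FittedModel(
        algorithm=spec.algorithm,
        estimator=estimator,
        feature_columns=list(features.feature_columns),
        best_params=best_params,
        cv_mean_auc=float(best_auc) if np.isfinite(best_auc) else float("nan"),
        seed=spec.seed,
    )


def predict_scores(model: FittedModel, features: FeatureTable) -> np.ndarray:
    """Per-pair association probabilities; columns must match training.

    Column names and order are part of the contract — a permuted or
    mismatched table raises a schema error naming the discrepancy.
    """
    if list(features.feature_columns) != model.feature_columns:
        missing = set(model.feature_columns) - set(features.feature_columns)
        extra = set(features.feature_columns) - set(model.feature_columns)
        raise ValueError(
            "feature columns do not match training columns "
            f"(missing: {sorted(missing)}, extra: {sorted(extra)}, "
            "or column order differs)"
        )
    if len(features) == 0:
        return np.empty(0, dtype=np.float64)
    return model.estimator.predict_proba(features.values())[:, 1]


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, list[tuple[float, float]]]:
    """AUC by the trapezoidal rule over the grouped-threshold ROC curve.

    Thresholds sweep the distinct score values, so tied scores move as one
    step and receive half credit — the result equals the Mann-Whitney
    pairwise statistic.  Requires both classes.
    """
    y = np.asarray(labels, dtype=np.int64)
    s = np.asarray(scores, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC is undefined with a single class")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    points = list(zip(fpr.tolist(), tpr.tolist()))
    if points[0] != (0.0, 0.0):
        points.insert(0, (0.0, 0.0))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return auc, points


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "FN", "TN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion_at_threshold(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> ConfusionCounts:
    y = np.asarray(labels, dtype=np.int64)
    pred = (np.asarray(scores, dtype=np.float64) >= threshold).astype(np.int64)
    return ConfusionCounts(
        TP=int(np.sum((pred == 1) & (y == 1))),
        FP=int(np.sum((pred == 1) & (y == 0))),
        FN=int(np.sum((pred == 0) & (y == 1))),
        TN=int(np.sum((pred == 0) & (y == 0))),
    )


def f1_score(confusion: ConfusionCounts) -> float:
    """F1 = 2TP / (2TP + FN + FP); defined as 0 when the denominator is 0."""
    denom = 2 * confusion.TP + confusion.FN + confusion.FP
    if denom == 0:
        warnings.warn("F1 denominator is zero (no positives predicted or present); returning 0")
        return 0.0
    return 2.0 * confusion.TP / denom


@dataclass
class EvaluationReport:
    auc: float
    f1: float
    threshold: float
    roc_points: list[tuple[float, float]]
    pr_points: list[tuple[float, float]]
    confusion: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "f1": self.f1,
            "threshold": self.threshold,
            "confusion": {
                "TP": self.confusion.TP,
                "FP": self.confusion.FP,
                "FN": self.confusion.FN,
                "TN": self.confusion.TN,
            },
        }


def evaluate(
    model: FittedModel,
    test_features: FeatureTable,
    test_labels: Sequence[int],
    threshold: float = 0.5,
) -> EvaluationReport:
    """Score the held-out pairs: AUC, F1 at ``threshold``, ROC and PR curves."""
    scores = predict_scores(model, test_features)
    return evaluate_scores(scores, test_labels, threshold)


def evaluate_scores(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> EvaluationReport:
    auc, roc_points = roc_auc(scores, labels)
    confusion = confusion_at_threshold(scores, labels, threshold)
    precision, recall, _ = precision_recall_curve(
        np.asarray(labels), np.asarray(scores)
    )
    pr_points = list(zip(recall.tolist(), precision.tolist()))
    return EvaluationReport(
        auc=auc,
        f1=f1_score(confusion),
        threshold=threshold,
        roc_points=roc_points,
        pr_points=pr_points,
        confusion=confusion,
    )
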