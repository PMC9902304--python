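"""Machine-learning sex classification: feature ranking, a fixed roster of
eight classical classifiers evaluated under stratified k-fold
cross-validation, and a stacked-generalization ensemble whose meta learner is
trained on out-of-fold class-probability vectors of the base learners.

Binary task throughout: male is the positive class (TP = male correctly
classified, TN = female correctly classified). Metrics are computed from the
confusion matrix accumulated over all held-out folds, so each case is tested
exactly once, and are reported in percent with a normal-approximation 95%
binomial confidence half-width 1.96 * sqrt(p(1-p)/n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from xgboost import XGBClassifier

from .cohort import VARIABLES

#: The eight comparison classifiers, by identifier.
CLASSIFIER_IDS = (
    "lda",
    "xgb",
    "random-forest",
    "logistic-regression",
    "extra-trees",
    "adaboost",
    "knn",
    "gradient-boosting",
)

RANKING_METHODS = ("xgboost-gain", "random-forest-impurity", "extra-trees-impurity")


def make_classifier(classifier_id: str, seed: int = 0):
    """Instantiate a roster classifier with library-default hyperparameters."""
    if classifier_id == "lda":
        return LinearDiscriminantAnalysis()
    if classifier_id == "xgb":
        return XGBClassifier(random_state=seed, eval_metric="logloss", verbosity=0)
    if classifier_id == "random-forest":
        return RandomForestClassifier(random_state=seed)
    if classifier_id == "logistic-regression":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if classifier_id == "extra-trees":
        return ExtraTreesClassifier(random_state=seed)
    if classifier_id == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if classifier_id == "knn":
        return KNeighborsClassifier()
    if classifier_id == "gradient-boosting":
        return GradientBoostingClassifier(random_state=seed)
    raise ValueError(f"unknown classifier id {classifier_id!r}")


def _xy(table: pd.DataFrame, features) -> tuple[np.ndarray, np.ndarray]:
    data = table[list(features) + ["sex"]].dropna()
    X = data[list(features)].to_numpy(dtype=float)
    y = (data["sex"].to_numpy() == "M").astype(int)  # male = positive class
    return X, y


def _zscore_train_apply(X_train, X_test):
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero training SD; cannot Z-score normalize")
    return (X_train - mu) / sd, (X_test - mu) / sd


# ---------------------------------------------------------------------------
# feature ranking


@dataclass
class FeatureRanking:
    method: str
    ranking: list[tuple[str, float]]  # (variable, importance), descending

    @property
    def ordered_variables(self) -> list[str]:
        return [v for v, _ in self.ranking]

    def top(self, k: int) -> list[str]:
        return self.ordered_variables[:k]


def rank_features(
    table: pd.DataFrame,
    method: str,
    features: tuple[str, ...] = VARIABLES,
    seed: int = 0,
) -> FeatureRanking:
    """Rank measurements by ensemble feature importance.

    Methods: ``xgboost-gain`` (boosted-tree gain importance),
    ``random-forest-impurity`` and ``extra-trees-impurity`` (mean impurity
    decrease). Ties break deterministically on variable name.
    """
    if method not in RANKING_METHODS:
        raise ValueError(f"unknown ranking method {method!r}; use {RANKING_METHODS}")
    X, y = _xy(table, features)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    if method == "xgboost-gain":
        model = XGBClassifier(
            random_state=seed, eval_metric="logloss", verbosity=0,
            importance_type="gain",
        )
    elif method == "random-forest-impurity":
        model = RandomForestClassifier(random_state=seed)
    else:
        model = ExtraTreesClassifier(random_state=seed)
    model.fit(X, y)
    scores = np.asarray(model.feature_importances_, dtype=float)
    order = sorted(zip(features, scores), key=lambda t: (-t[1], t[0]))
    return FeatureRanking(method=method, ranking=[(v, float(s)) for v, s in order])


# ---------------------------------------------------------------------------
# confusion matrix and metrics


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass
class Metric:
    """A metric in percent with its 95% CI half-width (also percent)."""

    value: float | None
    ci_half_width: float | None


@dataclass
class MetricSet:
    accuracy: Metric
    precision: Metric
    sensitivity: Metric
    specificity: Metric
    f1: Metric
    auc: Metric | None = None


def _ci_half_width(p: float, n: int) -> float:
    return 100.0 * 1.96 * np.sqrt(p * (1.0 - p) / n)


def _metric(num: int | float, den: int | float, n_eval: int) -> Metric:
    if den == 0:
        return Metric(None, None)
    p = num / den
    return Metric(100.0 * p, _ci_half_width(p, n_eval))


def compute_metrics(cm: ConfusionMatrix, n_eval: int | None = None) -> MetricSet:
    """Accuracy, precision, sensitivity, specificity and F1 from counts.

    F1 is the harmonic mean of precision and sensitivity. A zero denominator
    (e.g. no predicted males) leaves that metric undefined (None), never 0.
    CI half-widths use the binomial normal approximation at ``n_eval``
    evaluated cases (default: the confusion-matrix total).
    """
    if min(cm.tp, cm.tn, cm.fp, cm.fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    n = cm.n if n_eval is None else n_eval
    if n == 0:
        raise ValueError("empty confusion matrix")
    accuracy = _metric(cm.tp + cm.tn, cm.n, n)
    precision = _metric(cm.tp, cm.tp + cm.fp, n)
    sensitivity = _metric(cm.tp, cm.tp + cm.fn, n)
    specificity = _metric(cm.tn, cm.tn + cm.fp, n)
    if precision.value is None or sensitivity.value is None:
        f1 = Metric(None, None)
    elif precision.value + sensitivity.value == 0:
        f1 = Metric(None, None)
    else:
        p, s = precision.value / 100.0, sensitivity.value / 100.0
        f = 2 * p * s / (p + s)
        f1 = Metric(100.0 * f, _ci_half_width(f, n))
    return MetricSet(accuracy, precision, sensitivity, specificity, f1)


# ---------------------------------------------------------------------------
# cross-validated evaluation


@dataclass
class EvaluationResult:
    classifier_id: str
    features: tuple[str, ...]
    metrics: MetricSet
    confusion: ConfusionMatrix
    #: out-of-fold male-class probability per evaluated row (table order)
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)


def _check_stratifiable(y: np.ndarray, k: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both sexes must be present for stratified folds")
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} rows; cannot stratify into {k} folds"
        )


def crossval_evaluate(
    table: pd.DataFrame,
    classifier_id: str,
    features: tuple[str, ...] | list[str],
    k: int = 5,
    seed: int = 0,
) -> EvaluationResult:
    """Stratified k-fold evaluation of one roster classifier.

    Z-score normalization is fitted on each training split and applied to its
    held-out fold; the confusion matrix accumulates over all folds so every
    row is tested exactly once.
    """
    if classifier_id not in CLASSIFIER_IDS:
        raise ValueError(f"unknown classifier id {classifier_id!r}")
    features = tuple(features)
    if not features:
        raise ValueError("feature list is empty")
    X, y = _xy(table, features)
    _check_stratifiable(y, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=int)
    prob = np.empty(len(y), dtype=float)
    for train_idx, test_idx in skf.split(X, y):
        Xtr, Xte = _zscore_train_apply(X[train_idx], X[test_idx])
        clf = make_classifier(classifier_id, seed=seed)
        clf.fit(Xtr, y[train_idx])
        pred[test_idx] = clf.predict(Xte)
        prob[test_idx] = _male_probability(clf, Xte)
    cm = ConfusionMatrix.from_predictions(y, pred)
    metrics = compute_metrics(cm)
    _, auc_pct = roc_curve(prob, y)
    metrics.auc = Metric(auc_pct, None)
    return EvaluationResult(classifier_id, features, metrics, cm, prob, y)


def _male_probability(clf, X) -> np.ndarray:
    proba = clf.predict_proba(X)
    if np.any(~np.isfinite(proba)):
        raise ValueError("classifier produced non-finite class probabilities")
    col = list(clf.classes_).index(1)
    return proba[:, col]


# ---------------------------------------------------------------------------
# stacking


class _ArgmaxMeta:
    """Identity-like meta learner: argmax of the first probability block.

    With a single base learner this reduces stacking to that base learner's
    own out-of-fold prediction, a useful correctness probe.
    """

    classes_ = np.array([0, 1])

    def fit(self, X, y):
        return self

    def predict(self, X):
        return (X[:, 1] > X[:, 0]).astype(int)

    def predict_proba(self, X):
        return np.column_stack([X[:, 0], X[:, 1]])


def _make_meta(meta_id: str, seed: int):
    if meta_id == "argmax":
        return _ArgmaxMeta()
    return make_classifier(meta_id, seed=seed)


@dataclass
class StackingModel:
    """A fitted stacking ensemble with its out-of-fold bookkeeping.

    ``meta_features`` holds one row per training row and one probability
    column per (base learner, class) pair; ``fold_assignment[i]`` is the
    inner fold in which row i was held out, so every meta-feature row was
    predicted by base learners that never saw it in training.
    """

    base_ids: tuple[str, ...]
    meta_id: str
    fold_assignment: np.ndarray = field(repr=False)
    meta_features: np.ndarray = field(repr=False)
    base_models: list = field(repr=False)
    meta_model: object = field(repr=False)
    features: tuple[str, ...] = ()

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        blocks = [m.predict_proba((X - mu) / sd) for m, (mu, sd) in self.base_models]
        Z = np.hstack(blocks)
        return self.meta_model.predict_proba(Z)


def build_meta_features(
    X: np.ndarray,
    y: np.ndarray,
    base_ids: tuple[str, ...],
    inner_k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold class-probability meta-feature matrix.

    Rows align with the training rows; columns are the concatenated
    two-class probability vectors of each base learner, each predicted for a
    row only by models trained on inner folds excluding that row. Returns
    (meta_features, fold_assignment).
    """
    _check_stratifiable(y, inner_k)
    skf = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    Z = np.full((len(y), 2 * len(base_ids)), np.nan)
    fold_of = np.full(len(y), -1, dtype=int)
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        fold_of[va] = fold
        Xtr, Xva = _zscore_train_apply(X[tr], X[va])
        for b, base_id in enumerate(base_ids):
            clf = make_classifier(base_id, seed=seed)
            clf.fit(Xtr, y[tr])
            proba = clf.predict_proba(Xva)
            cols = [list(clf.classes_).index(0), list(clf.classes_).index(1)]
            Z[va, 2 * b : 2 * b + 2] = proba[:, cols]
    if np.any(~np.isfinite(Z)):
        raise ValueError("degenerate (non-finite) base-learner probabilities")
    return Z, fold_of


def fit_stacking(
    table: pd.DataFrame,
    base_ids: tuple[str, ...] | list[str],
    meta_id: str,
    features: tuple[str, ...] | list[str],
    inner_k: int = 5,
    seed: int = 0,
) -> StackingModel:
    """Fit a stacking ensemble on the whole table.

    Base learners are refit on all rows for deployment; the meta learner is
    trained on the out-of-fold probability matrix so it never sees a base
    prediction made on training data.
    """
    base_ids = tuple(base_ids)
    features = tuple(features)
    if not base_ids:
        raise ValueError("need at least one base learner")
    X, y = _xy(table, features)
    Z, fold_of = build_meta_features(X, y, base_ids, inner_k=inner_k, seed=seed)
    meta = _make_meta(meta_id, seed)
    meta.fit(Z, y)
    base_models = []
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Xn = (X - mu) / sd
    for base_id in base_ids:
        clf = make_classifier(base_id, seed=seed)
        clf.fit(Xn, y)
        base_models.append((clf, (mu, sd)))
    return StackingModel(
        base_ids=base_ids,
        meta_id=meta_id,
        fold_assignment=fold_of,
        meta_features=Z,
        base_models=base_models,
        meta_model=meta,
        features=features,
    )


def stack_fit_evaluate(
    table: pd.DataFrame,
    base_ids: tuple[str, ...] | list[str],
    meta_id: str,
    features: tuple[str, ...] | list[str],
    k: int = 5,
    inner_k: int = 5,
    seed: int = 0,
) -> tuple[EvaluationResult, StackingModel]:
    """Stratified k-fold evaluation of the stacking ensemble.

    Within each outer training partition: base learners are trained across
    ``inner_k`` stratified inner folds to produce out-of-fold probability
    meta-features; the meta learner is trained on those; for the outer test
    fold, base learners refit on the full outer-train predict probabilities
    that the meta learner maps to the final decision. The returned
    :class:`StackingModel` is the ensemble refit on the whole table.
    """
    base_ids = tuple(base_ids)
    features = tuple(features)
    if not base_ids:
        raise ValueError("need at least one base learner")
    X, y = _xy(table, features)
    _check_stratifiable(y, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=int)
    prob = np.empty(len(y), dtype=float)
    for tr, te in skf.split(X, y):
        Z_tr, _ = build_meta_features(X[tr], y[tr], base_ids, inner_k=inner_k, seed=seed)
        meta = _make_meta(meta_id, seed)
        meta.fit(Z_tr, y[tr])
        Xtr, Xte = _zscore_train_apply(X[tr], X[te])
        blocks = []
        for base_id in base_ids:
            clf = make_classifier(base_id, seed=seed)
            clf.fit(Xtr, y[tr])
            proba = clf.predict_proba(Xte)
            cols = [list(clf.classes_).index(0), list(clf.classes_).index(1)]
            blocks.append(proba[:, cols])
        Z_te = np.hstack(blocks)
        if np.any(~np.isfinite(Z_te)):
            raise ValueError("degenerate (non-finite) base-learner probabilities")
        pred[te] = meta.predict(Z_te)
        prob[te] = _male_probability(meta, Z_te)
    cm = ConfusionMatrix.from_predictions(y, pred)
    metrics = compute_metrics(cm)
    _, auc_pct = roc_curve(prob, y)
    metrics.auc = Metric(auc_pct, None)
    result = EvaluationResult(
        f"stacking[{'+'.join(base_ids)}->{meta_id}]", features, metrics, cm, prob, y
    )
    model = fit_stacking(table, base_ids, meta_id, features, inner_k=inner_k, seed=seed)
    return result, model


# ---------------------------------------------------------------------------
# ROC


def roc_curve(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC points and trapezoidal AUC (percent) for male-class probabilities.

    The trapezoidal AUC over all thresholds equals the normalized
    Mann–Whitney U statistic of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("need both classes present to compute a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return points, float(100.0 * _trapezoid_auc(fpr, tpr))
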