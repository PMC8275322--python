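"""Seeded evaluation protocol: stratified split, scaling, grid search, metrics.

The protocol, applied identically to every feature representation:

1. stratified 70/30 split (per-class test counts by rounding, seeded
   within-class shuffles);
2. per-feature min-max scaling to [0, 1] fit on the training rows only and
   reapplied to the test rows (never clipped; a constant training column
   maps everything to 0);
3. shallow hyperparameter grid search scored by mean AUC over two repeats
   of stratified six-fold cross-validation, ties broken by grid order;
4. refit on the full training set and a held-out metric suite: AUC, Brier
   loss, log loss, accuracy, F1, Youden's J (maximized over ROC
   thresholds), recall, precision, specificity.

Every stochastic stage draws its seed deterministically from one master
seed, so a configuration's result is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import CVError, SplitError, ValidationError
from .features import FeatureMatrix
from .util import derive_seed

__all__ = [
    "CLASSIFIERS",
    "SplitSpec",
    "MetricSet",
    "EvaluationResult",
    "default_grid",
    "stratified_split",
    "MinMaxScaler",
    "fit_minmax",
    "apply_scaler",
    "make_classifier",
    "grid_search",
    "roc_auc",
    "compute_metrics",
    "train_and_evaluate",
]

CLASSIFIERS = ("logreg", "svc", "random_forest", "gradient_boosted_trees")

# Shallow grids searched per classifier, in declared (tie-breaking) order.
_GRIDS: dict[str, list[dict]] = {
    "logreg": [{"C": c} for c in (0.1, 1, 10, 100)],
    "svc": [
        {"C": c, "kernel": k} for c in (0.1, 1, 10, 100) for k in ("linear", "poly", "rbf")
    ],
    "random_forest": [{"n_estimators": n} for n in (100, 500)],
    "gradient_boosted_trees": [{"n_estimators": n} for n in (100, 500)],
}


def default_grid(classifier: str) -> list[dict]:
    """The hyperparameter grid searched for a classifier, in declared order."""
    if classifier not in _GRIDS:
        raise ValidationError(f"unknown classifier {classifier!r}; choose from {CLASSIFIERS}")
    return [dict(p) for p in _GRIDS[classifier]]


# ---------------------------------------------------------------------------
# split and scaling


@dataclass
class SplitSpec:
    """A stratified train/test partition by row index."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    test_fraction: float


def stratified_split(labels, test_fraction: float = 0.30, seed: int = 0) -> SplitSpec:
    """Seeded stratified split with per-class test counts round(n_c * fraction)."""
    labels = np.asarray(labels, dtype=int).ravel()
    classes = np.unique(labels)
    if len(classes) < 2:
        raise SplitError("both classes must be present")
    if len(labels) < 4:
        raise SplitError("need at least 4 samples")
    if not 0 < test_fraction < 1:
        raise SplitError(f"test_fraction must lie in (0, 1), got {test_fraction}")

    rng = np.random.default_rng(derive_seed(seed, "stratified-split"))
    train_parts, test_parts = [], []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise SplitError(f"class {cls} has fewer than 2 members")
        n_test = int(round(len(idx) * test_fraction))
        if n_test == 0 or n_test == len(idx):
            raise SplitError(
                f"class {cls}: test_fraction {test_fraction} leaves an empty train or test side"
            )
        perm = rng.permutation(idx)
        test_parts.append(np.sort(perm[:n_test]))
        train_parts.append(np.sort(perm[n_test:]))
    return SplitSpec(
        train_idx=np.sort(np.concatenate(train_parts)),
        test_idx=np.sort(np.concatenate(test_parts)),
        seed=seed,
        test_fraction=test_fraction,
    )


class MinMaxScaler:
    """Per-feature [0, 1] scaling fit on training rows.

    x -> (x - min) / (max - min); a constant training column maps every
    value (train or test) to 0; test values are never clipped.
    """

    def __init__(self, minimum: np.ndarray, scale: np.ndarray):
        self.minimum = minimum
        self.scale = scale

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.minimum) * self.scale


def fit_minmax(train_values: np.ndarray) -> MinMaxScaler:
    train_values = np.atleast_2d(np.asarray(train_values, dtype=float))
    if train_values.shape[0] < 2:
        raise ValidationError("need at least 2 training rows to fit a scaler")
    lo = train_values.min(axis=0)
    span = train_values.max(axis=0) - lo
    scale = np.divide(1.0, span, out=np.zeros_like(span), where=span > 0)
    return MinMaxScaler(lo, scale)


def apply_scaler(scaler: MinMaxScaler, values: np.ndarray) -> np.ndarray:
    return scaler.transform(values)


# ---------------------------------------------------------------------------
# classifiers


def make_classifier(name: str, params: Mapping, seed: int):
    """Instantiate a classifier with grid parameters and a derived seed."""
    if name == "logreg":
        return LogisticRegression(max_iter=5000, random_state=seed, **params)
    if name == "svc":
        return SVC(probability=True, random_state=seed, **params)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if name == "gradient_boosted_trees":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed, n_jobs=1, verbosity=0, eval_metric="logloss", **params
        )
    raise ValidationError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def _scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous ranking score: margin when available, else P(class 1)."""
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


# ---------------------------------------------------------------------------
# metrics


def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney statistic (ties count one half)."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=int).ravel()
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC is undefined with a single class")
    ranks = rankdata(scores)
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class MetricSet:
    """Held-out metric suite for one evaluated configuration."""

    auc: float
    brier: float
    log_loss: float
    accuracy: float
    f1: float
    youden: float
    recall: float
    precision: float
    specificity: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def compute_metrics(scores, probabilities, labels) -> MetricSet:
    """Score one set of predictions.

    AUC is rank-based on the continuous scores; Brier and log loss use the
    probabilities (log loss floored at 1e-15); thresholded metrics classify
    at probability 0.5; Youden's J is maximized over ROC thresholds.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    probs = np.asarray(probabilities, dtype=float).ravel()
    labels = np.asarray(labels, dtype=int).ravel()
    if not (len(scores) == len(probs) == len(labels)):
        raise ValidationError("scores, probabilities and labels must have equal length")

    auc = roc_auc(scores, labels)
    brier = float(np.mean((probs - labels) ** 2))
    clipped = np.clip(probs, 1e-15, 1 - 1e-15)
    log_loss = float(-np.mean(labels * np.log(clipped) + (1 - labels) * np.log(1 - clipped)))

    pred = (probs >= 0.5).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    accuracy = (tp + tn) / len(labels)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0

    fpr, tpr, _ = roc_curve(labels, scores)
    youden = float(np.max(tpr - fpr))

    return MetricSet(
        auc=auc,
        brier=brier,
        log_loss=log_loss,
        accuracy=float(accuracy),
        f1=float(f1),
        youden=youden,
        recall=float(recall),
        precision=float(precision),
        specificity=float(specificity),
    )


# ---------------------------------------------------------------------------
# grid search and end-to-end evaluation


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    classifier: str,
    grid: Sequence[Mapping] | None = None,
    folds: int = 6,
    repeats: int = 2,
    seed: int = 0,
) -> tuple[dict, float]:
    """Select hyperparameters by mean CV AUC.

    Every grid point is scored by ``repeats`` repeats of stratified
    ``folds``-fold CV (repeat r reshuffles with a seed derived from the
    master seed and r); the mean of the folds*repeats fold AUCs decides,
    first-listed point winning ties.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    grid = list(grid) if grid is not None else default_grid(classifier)
    if not grid:
        raise ValidationError("empty hyperparameter grid")
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise CVError(
            f"smallest class has {counts.min()} samples, fewer than {folds} folds; "
            "reduce the fold count via config"
        )

    fold_plans = []
    for r in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=derive_seed(seed, f"cv-repeat-{r}")
        )
        fold_plans.extend(list(skf.split(X, y)))

    best_params, best_auc = None, -np.inf
    for params in grid:
        fold_aucs = []
        for k, (tr, va) in enumerate(fold_plans):
            model = make_classifier(classifier, params, derive_seed(seed, f"cv-fit-{k}"))
            model.fit(X[tr], y[tr])
            fold_aucs.append(roc_auc(_scores(model, X[va]), y[va]))
        mean_auc = float(np.mean(fold_aucs))
        if mean_auc > best_auc:
            best_params, best_auc = dict(params), mean_auc
    return best_params, best_auc


@dataclass
class EvaluationResult:
    """Outcome of one configuration: chosen hyperparameters, CV and test scores."""

    descriptor: dict
    classifier: str
    best_params: dict
    cv_auc: float
    metrics: MetricSet
    seed: int
    n_train: int
    n_test: int
    split: SplitSpec | None = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {
            "descriptor": dict(self.descriptor),
            "classifier": self.classifier,
            "best_params": dict(self.best_params),
            "cv_auc": self.cv_auc,
            "metrics": self.metrics.as_dict(),
            "seed": self.seed,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


def train_and_evaluate(
    matrix: FeatureMatrix,
    classifier: str = "logreg",
    grid: Sequence[Mapping] | None = None,
    test_fraction: float = 0.30,
    folds: int = 6,
    repeats: int = 2,
    seed: int = 0,
    descriptor: Mapping | None = None,
) -> EvaluationResult:
    """Run the full protocol on one feature matrix.

    Split, scale on train, grid-search by CV AUC, refit on the full
    training set, evaluate on the held-out rows. Deterministic given the
    master seed.
    """
    split = stratified_split(matrix.labels, test_fraction, seed=derive_seed(seed, "split"))
    X_train = matrix.values[split.train_idx]
    X_test = matrix.values[split.test_idx]
    y_train = matrix.labels[split.train_idx]
    y_test = matrix.labels[split.test_idx]

    scaler = fit_minmax(X_train)
    X_train = apply_scaler(scaler, X_train)
    X_test = apply_scaler(scaler, X_test)

    best_params, cv_auc = grid_search(
        X_train, y_train, classifier, grid=grid, folds=folds, repeats=repeats,
        seed=derive_seed(seed, "grid-search"),
    )
    model = make_classifier(classifier, best_params, derive_seed(seed, "refit"))
    model.fit(X_train, y_train)
    metrics = compute_metrics(
        _scores(model, X_test), model.predict_proba(X_test)[:, 1], y_test
    )
    return EvaluationResult(
        descriptor=dict(descriptor or {}),
        classifier=classifier,
        best_params=best_params,
        cv_auc=cv_auc,
        metrics=metrics,
        seed=seed,
        n_train=len(split.train_idx),
        n_test=len(split.test_idx),
        split=split,
    )
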