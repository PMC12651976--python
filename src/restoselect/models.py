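"""Classifier bank and the wrapper-fitness evaluator.

Conventional models are scikit-learn estimators configured to the study
hyperparameters: an RBF-kernel SVM (C=10, gamma=0.1, inverse-frequency
class weights, optional grid search), K-NN with k tuned over the odd
grid 3..11 (default k=5), a Gini decision tree of maximum depth 20, and
a 100-tree random forest.  A CNN baseline is deliberately not included:
the package targets the texture-feature pipeline and keeps its
dependency footprint to the scientific Python stack.

:class:`FitnessEvaluator` is the bridge to the feature-selection
optimizer: it holds *training-fold rows only* and scores a binary
feature mask by seeded stratified internal cross-validation of the SVM
on the selected columns, so wrapper fitness is a pure function of the
mask and the held-out data can never leak into selection.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .exceptions import ConfigError, FitnessError


@dataclasses.dataclass(frozen=True)
class SvmConfig:
    """RBF-SVM settings; stated values are used when grid search is off."""

    C: float = 10.0
    gamma: float = 0.1
    C_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0)
    class_weighted: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ConfigError("C and gamma must be > 0")


@dataclasses.dataclass(frozen=True)
class KnnConfig:
    k: int = 5
    k_grid: tuple[int, ...] = (3, 5, 7, 9, 11)

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ConfigError("k must be odd and >= 1")


@dataclasses.dataclass(frozen=True)
class TreeConfig:
    criterion: str = "gini"
    max_depth: int = 20


@dataclasses.dataclass(frozen=True)
class ForestConfig:
    n_estimators: int = 100
    max_depth: int = 20

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ConfigError("n_estimators must be >= 1")


@dataclasses.dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters for the whole classifier bank."""

    svm: SvmConfig = SvmConfig()
    knn: KnnConfig = KnnConfig()
    dt: TreeConfig = TreeConfig()
    rf: ForestConfig = ForestConfig()
    grid_search: bool = False
    internal_cv_folds: int = 3
    seed: int = 0


def _check_labels(y: np.ndarray) -> None:
    if np.unique(y).size < 2:
        raise ConfigError("training labels are degenerate (single class)")


def _svc(cfg: SvmConfig, C: float, gamma: float, seed: int) -> SVC:
    return SVC(
        kernel="rbf",
        C=C,
        gamma=gamma,
        class_weight="balanced" if cfg.class_weighted else None,
        random_state=seed,
    )


def grid_search_svm(
    X: np.ndarray,
    y: np.ndarray,
    folds: int,
    C_grid: Sequence[float],
    gamma_grid: Sequence[float],
    seed: int,
    class_weighted: bool = True,
) -> tuple[float, float]:
    """Pick (C, gamma) maximizing seeded stratified-CV accuracy.

    The grid is scanned in ascending (C, gamma) order and only strict
    improvements are kept, so ties resolve toward the smallest C, then
    the smallest gamma.
    """
    _check_labels(np.asarray(y))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    base = SvmConfig(class_weighted=class_weighted)
    best: tuple[float, float] | None = None
    best_score = -np.inf
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            score = cross_val_score(
                _svc(base, C, gamma, seed), X, y, cv=cv, scoring="accuracy"
            ).mean()
            if score > best_score:
                best_score = score
                best = (C, gamma)
    assert best is not None
    return best


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SvmConfig | None = None,
    seed: int = 0,
    grid_search: bool = False,
    folds: int = 3,
) -> SVC:
    """Fit the RBF-SVM (optionally grid searching C and gamma first)."""
    if cfg is None:
        cfg = SvmConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_labels(y)
    C, gamma = cfg.C, cfg.gamma
    if grid_search:
        C, gamma = grid_search_svm(
            X, y, folds, cfg.C_grid, cfg.gamma_grid, seed, cfg.class_weighted
        )
    return _svc(cfg, C, gamma, seed).fit(X, y)


def train_knn(
    X: np.ndarray,
    y: np.ndarray,
    cfg: KnnConfig | None = None,
    seed: int = 0,
    tune_k: bool = True,
    folds: int = 3,
) -> KNeighborsClassifier:
    """Fit K-NN; ``tune_k`` selects k from the odd grid by seeded CV."""
    if cfg is None:
        cfg = KnnConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_labels(y)
    k = cfg.k
    if tune_k and cfg.k_grid:
        if max(cfg.k_grid) > len(y):
            raise ConfigError("k grid exceeds the number of training rows")
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        best_score = -np.inf
        for cand in sorted(cfg.k_grid):
            score = cross_val_score(
                KNeighborsClassifier(n_neighbors=cand), X, y, cv=cv
            ).mean()
            if score > best_score:
                best_score = score
                k = cand
    if k > len(y):
        raise ConfigError(f"k={k} exceeds the number of training rows {len(y)}")
    return KNeighborsClassifier(n_neighbors=k).fit(X, y)


def train_dt(
    X: np.ndarray, y: np.ndarray, cfg: TreeConfig | None = None, seed: int = 0
) -> DecisionTreeClassifier:
    if cfg is None:
        cfg = TreeConfig()
    y = np.asarray(y)
    _check_labels(y)
    return DecisionTreeClassifier(
        criterion=cfg.criterion, max_depth=cfg.max_depth, random_state=seed
    ).fit(np.asarray(X, dtype=float), y)


def train_rf(
    X: np.ndarray, y: np.ndarray, cfg: ForestConfig | None = None, seed: int = 0
) -> RandomForestClassifier:
    if cfg is None:
        cfg = ForestConfig()
    y = np.asarray(y)
    _check_labels(y)
    return RandomForestClassifier(
        n_estimators=cfg.n_estimators,
        max_depth=cfg.max_depth,
        criterion="gini",
        random_state=seed,
    ).fit(np.asarray(X, dtype=float), y)


def predict(model, X: np.ndarray) -> np.ndarray:
    """Predict one label per row; empty input yields an empty array."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        return np.asarray([], dtype=object)
    return model.predict(X)


def predict_scores(model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-class scores normalized to sum 1 per row, plus the class order.

    Probabilistic models report ``predict_proba``; margin models (SVC)
    report a softmax over the one-vs-rest decision values — a normalized
    confidence ordering, not a calibrated probability.
    """
    X = np.asarray(X, dtype=float)
    classes = np.asarray(model.classes_)
    if X.shape[0] == 0:
        return np.zeros((0, classes.size)), classes
    if hasattr(model, "predict_proba"):
        scores = model.predict_proba(X)
    else:
        margins = model.decision_function(X)
        if margins.ndim == 1:  # binary: one margin column
            margins = np.column_stack([-margins, margins])
        margins = margins - margins.max(axis=1, keepdims=True)
        scores = np.exp(margins)
    return scores / scores.sum(axis=1, keepdims=True), classes


class FitnessEvaluator:
    """Seeded internal-CV accuracy of the SVM on mask-selected columns.

    Constructed from *training-fold* feature rows and labels only; it
    has no reference to held-out data by design.  ``accuracy(mask)`` is
    deterministic for a fixed (mask, seed) because the CV folds and the
    classifier seed are fixed at construction.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        n_folds: int = 3,
        svm: SvmConfig | None = None,
        seed: int = 0,
    ) -> None:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ConfigError("X and y row counts differ")
        if X.shape[0] < n_folds:
            raise ConfigError(
                f"{X.shape[0]} rows cannot support {n_folds}-fold internal CV"
            )
        _check_labels(y)
        self._X = X
        self._y = y
        self.n_features = X.shape[1]
        self.n_folds = n_folds
        self.svm = svm if svm is not None else SvmConfig()
        self.seed = seed
        # Folds are fixed once so accuracy is a pure function of the mask.
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        self._folds = list(cv.split(X, y))

    def accuracy(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if mask.size != self.n_features:
            raise FitnessError(
                f"mask length {mask.size} does not match {self.n_features} features"
            )
        if not mask.any():
            raise FitnessError("cannot evaluate an empty feature mask")
        Xm = self._X[:, mask]
        scores = []
        for train_idx, val_idx in self._folds:
            clf = _svc(self.svm, self.svm.C, self.svm.gamma, self.seed)
            clf.fit(Xm[train_idx], self._y[train_idx])
            scores.append(
                float(np.mean(clf.predict(Xm[val_idx]) == self._y[val_idx]))
            )
        return float(np.mean(scores))
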