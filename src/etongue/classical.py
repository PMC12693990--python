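"""Stratified splitting, grid search, and the tuned SVM / random-forest models.

The two classical classifiers use the tuned hyperparameters of the study:
a linear-kernel SVM with penalty C = 6 (one-vs-rest multiclass by default)
and a random forest with 64 trees, depth 8 and 8 features per split.  The
forest predicts by hard majority vote among its trees — each tree casts one
vote and ties break toward the lowest class label — with the per-tree votes
exposed for audit.  Model fitting stands on scikit-learn; the split and the
grid search are thin deterministic wrappers so that seeds, tie-breaks and the
full cross-validation score table are part of the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

__all__ = [
    "SplitIndices",
    "SVMConfig",
    "RFConfig",
    "TrainedClassifier",
    "split_dataset",
    "train_svm",
    "train_rf",
    "tree_votes",
    "grid_search",
    "GridSearchResult",
]


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint stratified train/test row indices covering all rows."""

    train_rows: np.ndarray
    test_rows: np.ndarray
    train_fraction: float
    seed: int


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "linear"
    C: float = 6.0
    gamma: object = "auto"
    multiclass: str = "ovr"  # one-vs-rest default; "ovo" uses SVC's native scheme

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError(f"C must be > 0, got {self.C}")
        if self.kernel not in ("linear", "rbf", "poly"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.multiclass not in ("ovr", "ovo"):
            raise ValueError(f"multiclass must be 'ovr' or 'ovo', got {self.multiclass!r}")


@dataclass(frozen=True)
class RFConfig:
    n_estimators: int = 64
    max_depth: int = 8
    max_features: object = 8

    def __post_init__(self) -> None:
        if self.n_estimators < 1 or (self.max_depth or 1) < 1:
            raise ValueError("n_estimators and max_depth must be >= 1")


@dataclass(frozen=True)
class TrainedClassifier:
    """A fitted model with a fixed ascending class order and a predict contract."""

    model_kind: str
    estimator: object
    class_labels: tuple

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model_kind == "rf":
            return _majority_vote(tree_votes(self, X), self.class_labels)
        return self.estimator.predict(X)


def split_dataset(y: Sequence, fraction: float = 0.8, seed: int = 42) -> SplitIndices:
    """Stratified train/test partition, reproducible under ``seed``.

    Per class, ``round(fraction * n_class)`` rows go to train, so per-class
    proportions are within one sample of the global fraction.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    y = np.asarray(y)
    rng = np.random.default_rng(int(seed))
    train, test = [], []
    for label in sorted(set(y.tolist())):
        rows = np.flatnonzero(y == label)
        if len(rows) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 members")
        rows = rng.permutation(rows)
        n_train = int(round(fraction * len(rows)))
        n_train = min(max(n_train, 1), len(rows) - 1)  # both sides non-empty
        train.append(rows[:n_train])
        test.append(rows[n_train:])
    return SplitIndices(
        train_rows=np.sort(np.concatenate(train)),
        test_rows=np.sort(np.concatenate(test)),
        train_fraction=fraction,
        seed=seed,
    )


def _check_classes(y: np.ndarray) -> tuple:
    classes = tuple(sorted(set(np.asarray(y).tolist())))
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes to train, got {classes}")
    return classes


def train_svm(
    X: np.ndarray, y: Sequence, cfg: SVMConfig = SVMConfig(), seed: int = 42
) -> TrainedClassifier:
    """Fit the (default linear, C=6) support-vector machine."""
    y = np.asarray(y)
    classes = _check_classes(y)
    base = SVC(kernel=cfg.kernel, C=cfg.C, gamma=cfg.gamma, random_state=seed)
    est = OneVsRestClassifier(base) if cfg.multiclass == "ovr" else base
    est.fit(X, y)
    return TrainedClassifier(model_kind="svm", estimator=est, class_labels=classes)


def train_rf(
    X: np.ndarray, y: Sequence, cfg: RFConfig = RFConfig(), seed: int = 42
) -> TrainedClassifier:
    """Fit the (default 64-tree, depth-8, 8-features) random forest."""
    y = np.asarray(y)
    classes = _check_classes(y)
    est = RandomForestClassifier(
        n_estimators=cfg.n_estimators,
        max_depth=cfg.max_depth,
        max_features=cfg.max_features,
        random_state=seed,
    )
    est.fit(X, y)
    return TrainedClassifier(model_kind="rf", estimator=est, class_labels=classes)


def tree_votes(clf: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Per-tree predicted labels, shape (n_trees, n_rows), for audit."""
    if clf.model_kind != "rf":
        raise ValueError("tree votes are defined for random forests only")
    est = clf.estimator
    return np.stack(
        [est.classes_[t.predict(X).astype(int)] for t in est.estimators_]
    )


def _majority_vote(votes: np.ndarray, class_labels: tuple) -> np.ndarray:
    """Majority vote per column; ties break toward the lowest class label."""
    labels = np.asarray(class_labels)
    counts = np.stack([(votes == c).sum(axis=0) for c in labels])
    return labels[counts.argmax(axis=0)]


@dataclass(frozen=True)
class GridSearchResult:
    best_config: object
    best_score: float
    table: pd.DataFrame  # one row per candidate, in input order


def grid_search(
    X: np.ndarray,
    y: Sequence,
    candidates: Sequence,
    folds: int = 5,
    seed: int = 42,
) -> GridSearchResult:
    """Exhaustive stratified k-fold cross-validated accuracy over candidates.

    ``candidates`` holds :class:`SVMConfig` and/or :class:`RFConfig` objects.
    Ties break toward the first-listed candidate; the full score table is
    returned for inspection.
    """
    if not candidates:
        raise ValueError("candidate grid must be non-empty")
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if folds > counts.min():
        raise ValueError(
            f"folds = {folds} exceeds smallest class size {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    rows = []
    for cfg in candidates:
        trainer = train_svm if isinstance(cfg, SVMConfig) else train_rf
        fold_acc = []
        for tr, te in splits:
            clf = trainer(X[tr], y[tr], cfg, seed=seed)
            fold_acc.append(float(np.mean(clf.predict(X[te]) == y[te])))
        rows.append({"config": cfg, "cv_accuracy": float(np.mean(fold_acc))})
    table = pd.DataFrame(rows)
    best_idx = int(table["cv_accuracy"].to_numpy().argmax())  # first max wins
    return GridSearchResult(
        best_config=table.loc[best_idx, "config"],
        best_score=float(table.loc[best_idx, "cv_accuracy"]),
        table=table,
    )


#: Default search grids bracketing the tuned optima.
DEFAULT_SVM_GRID = tuple(
    SVMConfig(kernel=k, C=c) for k in ("linear", "rbf") for c in (0.1, 1, 6, 10, 100)
)
DEFAULT_RF_GRID = tuple(
    RFConfig(n_estimators=n, max_depth=d, max_features=f)
    for n in (16, 32, 64, 128)
    for d in (4, 8, 16)
    for f in (4, 8, 16, "sqrt")
)
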