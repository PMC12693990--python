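"""Accuracy, confusion matrices, cross-model comparison and LDA visualization.

The Fisher linear discriminant analysis used for the 2-D class map is solved
from the between-class and within-class scatter matrices, with a small ridge
added to the within-class scatter when it is singular (as happens whenever the
feature dimension exceeds the sample count).  Class centroids in score space
are exact class means, and the 95% regions are covariance ellipses scaled by
the 0.95 quantile of a chi-square distribution with 2 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import chi2
from sklearn.metrics import confusion_matrix

__all__ = [
    "EvalReport",
    "LDAProjection",
    "Ellipse",
    "score_predictions",
    "compare_models",
    "lda_fit_project",
    "ellipse_95",
    "plot_confusion",
    "plot_lda",
    "plot_accuracy_bars",
]


@dataclass(frozen=True)
class EvalReport:
    """Test-set scoreboard for one (model, feature) combination.

    Confusion rows are true classes, columns predicted, both in ascending
    class order.
    """

    model_kind: str
    feature_kind: str
    n_test: int
    accuracy: float
    confusion: np.ndarray
    misclassified: int
    class_order: tuple = ()


@dataclass(frozen=True)
class Ellipse:
    center: np.ndarray  # (2,)
    semi_axes: np.ndarray  # (2,) descending
    angle: float  # radians, orientation of the major axis


@dataclass(frozen=True)
class LDAProjection:
    scores: np.ndarray  # (N, 2)
    centroids: np.ndarray  # (C, 2)
    ellipses: tuple  # per-class Ellipse
    class_order: tuple
    y: np.ndarray = field(repr=False, default=None)


def score_predictions(
    y_true: Sequence,
    y_pred: Sequence,
    class_order: Sequence,
    model_kind: str = "",
    feature_kind: str = "",
) -> EvalReport:
    """Accuracy + confusion matrix (rows true / columns predicted)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    order = list(class_order)
    cm = confusion_matrix(y_true, y_pred, labels=order)
    n = len(y_true)
    correct = int(np.trace(cm))
    return EvalReport(
        model_kind=model_kind,
        feature_kind=feature_kind,
        n_test=n,
        accuracy=correct / n,
        confusion=cm,
        misclassified=n - correct,
        class_order=tuple(order),
    )


def compare_models(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """Ranked comparison, accuracy descending, ties broken by model name."""
    if not reports:
        raise ValueError("no reports to compare")
    df = pd.DataFrame(
        {
            "model": [r.model_kind for r in reports],
            "features": [r.feature_kind for r in reports],
            "n_test": [r.n_test for r in reports],
            "accuracy": [r.accuracy for r in reports],
            "misclassified": [r.misclassified for r in reports],
        }
    )
    return df.sort_values(
        ["accuracy", "model"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def lda_fit_project(
    X: np.ndarray, y: Sequence, n_components: int = 2, ridge: float = 1e-6
) -> LDAProjection:
    """Fisher discriminant projection to ``n_components`` axes with per-class
    centroids and 95% covariance ellipses.

    The within-class scatter is regularized as ``Sw + ridge * tr(Sw)/d * I``
    before the generalized eigenproblem is solved, which keeps the projection
    defined when d >= N (e.g. raw 10080-sample signals).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = tuple(sorted(set(y.tolist())))
    C = len(classes)
    if C < 2:
        raise ValueError("LDA requires at least two classes")
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError(f"X must be N x d with d >= 2, got {X.shape}")
    if n_components > C - 1:
        raise ValueError(
            f"at most C - 1 = {C - 1} discriminant axes are meaningful; "
            f"requested {n_components}"
        )
    d = X.shape[1]
    grand = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in classes:
        Xc = X[y == c]
        mu = Xc.mean(axis=0)
        dev = Xc - mu
        Sw += dev.T @ dev
        dm = (mu - grand)[:, None]
        Sb += len(Xc) * (dm @ dm.T)
    scale = np.trace(Sw) / d
    Sw_reg = Sw + ridge * (scale if scale > 0 else 1.0) * np.eye(d)
    evals, evecs = scipy.linalg.eigh(Sb, Sw_reg)
    order = np.argsort(evals)[::-1]
    V = evecs[:, order[:n_components]]
    scores = (X - grand) @ V
    centroids = np.stack([scores[y == c].mean(axis=0) for c in classes])
    # confidence ellipses are a 2-D construct; skip them for 1-axis projections
    ellipses = (
        tuple(ellipse_95(scores[y == c]) for c in classes)
        if n_components == 2
        else ()
    )
    return LDAProjection(
        scores=scores,
        centroids=centroids,
        ellipses=ellipses,
        class_order=classes,
        y=y,
    )


def ellipse_95(scores: np.ndarray) -> Ellipse:
    """95% covariance ellipse of a 2-D point cloud.

    Semi-axes are ``sqrt(eigenvalue * chi2.ppf(0.95, df=2))`` of the sample
    covariance; the angle orients the major axis.  A degenerate covariance
    floors the semi-axes at machine epsilon with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError(f"scores must be N x 2, got {scores.shape}")
    if len(scores) < 3:
        raise ValueError(f"need >= 3 points for an ellipse, got {len(scores)}")
    center = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    evals = evals[::-1]
    evecs = evecs[:, ::-1]
    q = chi2.ppf(0.95, df=2)
    eps = np.finfo(float).eps
    if np.any(evals <= eps):
        warnings.warn("degenerate class covariance; ellipse semi-axes floored")
        evals = np.maximum(evals, eps)
    semi = np.sqrt(evals * q)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return Ellipse(center=center, semi_axes=semi, angle=angle)


# ---------------------------------------------------------------------------
# plotting (all writers take a path and save a figure)


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_confusion(report: EvalReport, path) -> None:
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(report.confusion, cmap="Blues")
    order = report.class_order
    ax.set_xticks(range(len(order)), order)
    ax.set_yticks(range(len(order)), order)
    ax.set_xlabel("predicted vintage")
    ax.set_ylabel("true vintage")
    for i in range(len(order)):
        for j in range(len(order)):
            ax.text(j, i, str(report.confusion[i, j]), ha="center", va="center")
    ax.set_title(f"{report.model_kind} / {report.feature_kind} "
                 f"(acc {report.accuracy:.3f})")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_lda(proj: LDAProjection, path) -> None:
    """Score scatter with 'x' centroids and 95% ellipses, one color per class."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    theta = np.linspace(0, 2 * np.pi, 200)
    for ci, c in enumerate(proj.class_order):
        pts = proj.scores[proj.y == c]
        (line,) = ax.plot(pts[:, 0], pts[:, 1], ".", ms=4, alpha=0.6, label=str(c))
        color = line.get_color()
        ax.plot(*proj.centroids[ci], "x", ms=10, mew=2.5, color=color)
        e = proj.ellipses[ci]
        ring = np.stack([e.semi_axes[0] * np.cos(theta), e.semi_axes[1] * np.sin(theta)])
        rot = np.array(
            [[np.cos(e.angle), -np.sin(e.angle)], [np.sin(e.angle), np.cos(e.angle)]]
        )
        xy = rot @ ring + e.center[:, None]
        ax.plot(xy[0], xy[1], "-", lw=1.2, color=color)
    ax.set_xlabel("LD1")
    ax.set_ylabel("LD2")
    ax.legend(title="vintage", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_accuracy_bars(comparison: pd.DataFrame, path) -> None:
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    labels = [f"{m}\n{f}" for m, f in zip(comparison["model"], comparison["features"])]
    ax.bar(range(len(comparison)), comparison["accuracy"], color="steelblue")
    ax.set_xticks(range(len(comparison)), labels, fontsize=7)
    ax.set_ylabel("test accuracy")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
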