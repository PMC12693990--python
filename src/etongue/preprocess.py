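"""Min-max normalization and classifier input layouts.

Normalization maps each feature (column) of the response matrix to

    x_scaled = (x - x_min) / (x_max - x_min)

with the column minimum and maximum taken from the data the scaler was fitted
on.  On the fitted data every non-constant column lands exactly in [0, 1];
held-out values outside the fitted range are NOT clipped.  Constant columns
(x_max == x_min) map to 0.  Because the statistics are per-column, adding any
constant to a column — such as the instrument's uniform ~28 mA baseline — or
rescaling it by a positive factor leaves the normalized output unchanged after
refitting: constant offsets are non-informative to everything downstream.

The default fitting scope is ``train_only`` (fit on the training split, apply
to both splits) to avoid leakage; ``all`` is retained for fitting on the full
matrix.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "NormalizationStats",
    "fit_normalization",
    "apply_normalization",
    "to_cnn_input",
    "stats_to_yaml",
    "stats_from_yaml",
]

_SCOPES = ("train_only", "all")


@dataclass(frozen=True)
class NormalizationStats:
    """Per-column minimum/maximum recorded at fit time, plus the fitting scope."""

    x_min: np.ndarray
    x_max: np.ndarray
    fitted_on: str = "train_only"

    def __post_init__(self) -> None:
        if self.fitted_on not in _SCOPES:
            raise ValueError(f"fitted_on must be one of {_SCOPES}, got {self.fitted_on!r}")
        if self.x_min.shape != self.x_max.shape:
            raise ValueError("x_min and x_max must have identical shape")
        if np.any(self.x_min > self.x_max):
            raise ValueError("x_min must be <= x_max elementwise")

    @property
    def n_features(self) -> int:
        return self.x_min.shape[0]


def fit_normalization(X: np.ndarray, scope: str = "train_only") -> NormalizationStats:
    """Record columnwise min and max of ``X`` (N x d, N >= 1)."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError(f"X must be a non-empty N x d matrix, got shape {X.shape}")
    return NormalizationStats(
        x_min=X.min(axis=0), x_max=X.max(axis=0), fitted_on=scope
    )


def apply_normalization(X: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Map each entry to (x - x_min) / (x_max - x_min); constant columns -> 0."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != stats.n_features:
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"stats were fitted on {stats.n_features}"
        )
    span = stats.x_max - stats.x_min
    safe = np.where(span == 0, 1.0, span)
    out = (X - stats.x_min) / safe
    if np.any(span == 0):
        out[:, span == 0] = 0.0
    return out


def to_cnn_input(
    X: np.ndarray, layout: str = "concat_1ch", n_channels: int = 6
) -> np.ndarray:
    """Reshape a (normalized) N x d matrix into a CNN batch.

    ``concat_1ch`` -> (N, d, 1): the horizontally concatenated multichannel
    signal as a single sequence.  ``multi_6ch`` -> (N, d / n_channels,
    n_channels) with channels in the fixed electrode order; flattening that
    layout channel-major recovers ``concat_1ch`` exactly.
    """
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError(f"X must be a non-empty N x d matrix, got shape {X.shape}")
    if layout == "concat_1ch":
        return X[:, :, None]
    if layout == "multi_6ch":
        n, d = X.shape
        if d % n_channels:
            raise ValueError(f"d = {d} not divisible by n_channels = {n_channels}")
        return X.reshape(n, n_channels, d // n_channels).transpose(0, 2, 1)
    raise ValueError(f"unknown layout {layout!r}; expected 'concat_1ch' or 'multi_6ch'")


def stats_to_yaml(stats: NormalizationStats, path=None) -> str:
    """Serialize stats to YAML (lists of floats) for audit."""
    payload = {
        "fitted_on": stats.fitted_on,
        "x_min": [float(v) for v in stats.x_min],
        "x_max": [float(v) for v in stats.x_max],
    }
    text = yaml.safe_dump(payload, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def stats_from_yaml(source) -> NormalizationStats:
    payload = yaml.safe_load(source if hasattr(source, "read") or "\n" in str(source)
                             else io.open(source).read())
    return NormalizationStats(
        x_min=np.asarray(payload["x_min"], dtype=float),
        x_max=np.asarray(payload["x_max"], dtype=float),
        fitted_on=payload.get("fitted_on", "train_only"),
    )
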