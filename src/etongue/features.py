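"""Per-pulse feature extraction for the classical classifiers.

Each voltage plateau of the excitation ladder contributes three engineered
descriptors of the electrode's current response:

* AREA — trapezoid-rule integral of the first 20 samples after the pulse edge
  (where the charging transient lives), with unit sample spacing;
* MAX / MIN — extrema over the full 40-sample plateau.

ORIGINAL is the untouched normalized concatenated signal.  Under the default
waveform the plateau kinds give 6 electrodes x 42 plateaus = 252 columns;
ORIGINAL keeps 6 x 1680 = 10080.  Columns are ordered electrode-major, then
plateau-ascending (or sample-ascending for ORIGINAL).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import NormalizationStats, apply_normalization
from .simulate import Dataset
from .waveform import build_waveform, plateau_slices

__all__ = [
    "FEATURE_KINDS",
    "FeatureTable",
    "plateau_area",
    "plateau_extrema",
    "build_feature_table",
]

FEATURE_KINDS = ("AREA", "MAX", "MIN", "ORIGINAL")


@dataclass(frozen=True)
class FeatureTable:
    """N x d feature matrix with its column provenance.

    ``column_index`` holds (electrode, plateau) pairs for the plateau kinds and
    (electrode, sample) pairs for ORIGINAL.
    """

    kind: str
    matrix: np.ndarray
    column_index: tuple[tuple[str, int], ...]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{e}_{self.kind}_{p}" for e, p in self.column_index]
        return pd.DataFrame(self.matrix, columns=cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def plateau_area(
    signal: np.ndarray, slices: Sequence[tuple[int, int]], window: int = 20
) -> np.ndarray:
    """Trapezoid integral of the first ``window`` samples of each plateau.

    Unit (sample-index) spacing: for a constant signal c the area over a
    20-point window is exactly 19*c.
    """
    signal = np.asarray(signal)
    lengths = [stop - start for start, stop in slices]
    if any(window > L for L in lengths):
        raise ValueError(
            f"window = {window} exceeds plateau length {min(lengths)}"
        )
    out = np.empty(len(slices))
    for p, (start, _stop) in enumerate(slices):
        seg = signal[start : start + window]
        out[p] = np.trapezoid(seg)
    return out


def plateau_extrema(
    signal: np.ndarray, slices: Sequence[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """(per-plateau max, per-plateau min) over all samples of each plateau."""
    signal = np.asarray(signal)
    mx = np.empty(len(slices))
    mn = np.empty(len(slices))
    for p, (start, stop) in enumerate(slices):
        seg = signal[start:stop]
        mx[p] = seg.max()
        mn[p] = seg.min()
    return mx, mn


def _plateau_view(Xn: np.ndarray, n_electrodes: int, n_plateaus: int, spp: int) -> np.ndarray:
    """(N, d) normalized matrix -> (N, electrodes, plateaus, samples_per_plateau)."""
    n = Xn.shape[0]
    return Xn.reshape(n, n_electrodes, n_plateaus, spp)


def build_feature_table(
    ds: Dataset,
    kind: str,
    stats: NormalizationStats,
    window: int = 20,
) -> FeatureTable:
    """Normalize the dataset's concatenated matrix, then extract ``kind``.

    The extraction is rowwise (no cross-sample coupling); column ordering is
    electrode-major then plateau-ascending, matching :data:`ELECTRODE_NAMES`.
    """
    if kind not in FEATURE_KINDS:
        raise ValueError(f"kind must be one of {FEATURE_KINDS}, got {kind!r}")
    Xn = apply_normalization(ds.X_concat, stats)
    names = ds.electrode_names
    if kind == "ORIGINAL":
        L = ds.n_samples_per_electrode
        cols = tuple((e, i) for e in names for i in range(L))
        return FeatureTable(kind=kind, matrix=Xn, column_index=cols)

    w = build_waveform(ds.waveform_spec)
    spp = w.samples_per_plateau
    P = w.n_plateaus
    if window > spp:
        raise ValueError(f"window = {window} exceeds samples_per_plateau = {spp}")
    view = _plateau_view(Xn, len(names), P, spp)
    if kind == "AREA":
        seg = view[..., :window]
        vals = np.trapezoid(seg, axis=-1)
    elif kind == "MAX":
        vals = view.max(axis=-1)
    else:  # MIN
        vals = view.min(axis=-1)
    cols = tuple((e, p) for e in names for p in range(P))
    return FeatureTable(kind=kind, matrix=vals.reshape(Xn.shape[0], -1), column_index=cols)
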