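"""MLAPV excitation waveform construction and indexing.

Multi-frequency large-amplitude pulse voltammetry (MLAPV) drives every working
electrode of the sensor array with the same stepped-voltage pulse train: a
ladder of constant-voltage plateaus, each held for a fixed duration and sampled
on a uniform grid.  The default protocol steps from -1 V to +1 V in 0.1 V
increments, holding each level for 0.1 s (40 samples at 400 Hz) and returning
to a 0 V recovery plateau after every level, which yields 21 levels x 2 = 42
plateaus and 42 x 40 = 1680 samples per electrode.  A 2 s 0 V hold follows the
train for electrode desorption; it is part of the protocol but contributes no
samples.

The plateau ordering within the ladder is a documented convention of this
package (ascending levels, each paired with a 0 V recovery plateau): it is the
simplest scheme consistent with the published plateau and sample counts.  An
explicit level list can be supplied via ``ladder_scheme="custom"``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "WaveformSpec",
    "ExcitationWaveform",
    "build_waveform",
    "voltage_at_sample",
    "plateau_slices",
    "waveform_to_csv",
    "spec_to_yaml",
    "spec_from_yaml",
]

_LADDER_SCHEMES = ("paired_with_recovery", "custom")


@dataclass(frozen=True)
class WaveformSpec:
    """Parameters of the MLAPV excitation protocol.

    Voltages in volts, durations in seconds.  ``custom_levels`` is the explicit
    plateau-level sequence used when ``ladder_scheme="custom"``.
    """

    v_min: float = -1.0
    v_max: float = 1.0
    v_step: float = 0.1
    plateau_duration: float = 0.1
    samples_per_plateau: int = 40
    hold_duration: float = 2.0
    ladder_scheme: str = "paired_with_recovery"
    custom_levels: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.ladder_scheme not in _LADDER_SCHEMES:
            raise ValueError(
                f"ladder_scheme must be one of {_LADDER_SCHEMES}, got {self.ladder_scheme!r}"
            )
        if self.ladder_scheme == "custom":
            if not self.custom_levels:
                raise ValueError("ladder_scheme='custom' requires a non-empty custom_levels")
        else:
            if self.v_min > self.v_max:
                raise ValueError(f"v_min ({self.v_min}) must not exceed v_max ({self.v_max})")
            if self.v_step <= 0:
                raise ValueError(f"v_step must be > 0, got {self.v_step}")
        if self.plateau_duration <= 0:
            raise ValueError(f"plateau_duration must be > 0, got {self.plateau_duration}")
        if self.samples_per_plateau < 1:
            raise ValueError(f"samples_per_plateau must be >= 1, got {self.samples_per_plateau}")
        if self.hold_duration < 0:
            raise ValueError(f"hold_duration must be >= 0, got {self.hold_duration}")

    @property
    def sampling_interval(self) -> float:
        """Seconds between consecutive samples within a plateau."""
        return self.plateau_duration / self.samples_per_plateau


@dataclass(frozen=True)
class ExcitationWaveform:
    """A fully expanded plateau-indexed and sample-indexed voltage sequence."""

    plateau_levels: np.ndarray  # (P,) volts
    samples: np.ndarray  # (P * samples_per_plateau,) volts
    plateau_start_indices: np.ndarray  # (P,) 0-based sample indices
    samples_per_plateau: int
    spec: WaveformSpec = field(repr=False)

    @property
    def n_plateaus(self) -> int:
        return len(self.plateau_levels)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_times(self) -> np.ndarray:
        """Elapsed time (s) of each sample from the start of the first plateau."""
        return np.arange(self.n_samples) * self.spec.sampling_interval


def _ladder_levels(spec: WaveformSpec) -> np.ndarray:
    """Ascending voltage levels of the ladder, validated for commensurate step."""
    span = spec.v_max - spec.v_min
    n_steps = span / spec.v_step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(
            f"(v_max - v_min) = {span} is not an integer multiple of v_step = {spec.v_step}"
        )
    n_levels = int(round(n_steps)) + 1
    levels = spec.v_min + spec.v_step * np.arange(n_levels)
    # snap exact zero: -1.0 + 10*0.1 accumulates no visible error but keep it clean
    levels[np.abs(levels) < 1e-12] = 0.0
    return levels


def build_waveform(spec: WaveformSpec) -> ExcitationWaveform:
    """Expand a :class:`WaveformSpec` into the full applied-voltage sequence.

    Under ``paired_with_recovery`` each ascending ladder level is followed by a
    0 V recovery plateau; the trailing hold is not sampled.  The function is
    pure: identical specs give bit-identical waveforms.
    """
    if spec.ladder_scheme == "paired_with_recovery":
        levels = _ladder_levels(spec)
        plateau_levels = np.empty(2 * len(levels))
        plateau_levels[0::2] = levels
        plateau_levels[1::2] = 0.0
    else:
        plateau_levels = np.asarray(spec.custom_levels, dtype=float)

    n = spec.samples_per_plateau
    samples = np.repeat(plateau_levels, n)
    starts = np.arange(len(plateau_levels)) * n
    return ExcitationWaveform(
        plateau_levels=plateau_levels,
        samples=samples,
        plateau_start_indices=starts,
        samples_per_plateau=n,
        spec=spec,
    )


def voltage_at_sample(w: ExcitationWaveform, i: int) -> float:
    """Plateau level owning sample ``i`` (0-based)."""
    if not 0 <= i < w.n_samples:
        raise IndexError(f"sample index {i} out of range [0, {w.n_samples})")
    return float(w.plateau_levels[i // w.samples_per_plateau])


def plateau_slices(w: ExcitationWaveform) -> list[tuple[int, int]]:
    """Half-open ``(start, stop)`` sample ranges, one per plateau, partitioning
    ``[0, n_samples)`` in order."""
    n = w.samples_per_plateau
    return [(int(s), int(s) + n) for s in w.plateau_start_indices]


def waveform_to_csv(w: ExcitationWaveform, path) -> None:
    """Write the expanded waveform as two-column CSV (sample_index, voltage_V)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_index", "voltage_V"])
        for i, v in enumerate(w.samples):
            writer.writerow([i, repr(float(v))])


def spec_to_yaml(spec: WaveformSpec, path=None) -> str:
    """Serialize a spec to YAML; writes to ``path`` if given, returns the text."""
    payload = {
        "v_min": spec.v_min,
        "v_max": spec.v_max,
        "v_step": spec.v_step,
        "plateau_duration": spec.plateau_duration,
        "samples_per_plateau": spec.samples_per_plateau,
        "hold_duration": spec.hold_duration,
        "ladder_scheme": spec.ladder_scheme,
        "custom_levels": list(spec.custom_levels) if spec.custom_levels else None,
    }
    text = yaml.safe_dump(payload, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def spec_from_yaml(source) -> WaveformSpec:
    """Load a spec from a YAML string or file path."""
    if isinstance(source, str) and "\n" not in source and source.endswith((".yml", ".yaml")):
        with open(source) as fh:
            payload = yaml.safe_load(fh)
    else:
        payload = yaml.safe_load(source)
    custom = payload.get("custom_levels")
    return WaveformSpec(
        v_min=payload.get("v_min", -1.0),
        v_max=payload.get("v_max", 1.0),
        v_step=payload.get("v_step", 0.1),
        plateau_duration=payload.get("plateau_duration", 0.1),
        samples_per_plateau=payload.get("samples_per_plateau", 40),
        hold_duration=payload.get("hold_duration", 2.0),
        ladder_scheme=payload.get("ladder_scheme", "paired_with_recovery"),
        custom_levels=tuple(custom) if custom else None,
    )
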