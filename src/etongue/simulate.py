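"""Synthetic six-electrode current responses with vintage-dependent structure.

The instrument's raw data are not public, so this module generates a
statistical stand-in with the structure the signals are described to have:

* a uniform non-Faradaic baseline of ~28 mA on every channel (an artifact of
  the two-electrode front end, identical across electrodes and classes);
* a predominantly ohmic component, current proportional to the applied plateau
  voltage through an electrode-specific conductance;
* a first-order step transient at every plateau edge, with electrode-specific
  amplitude and time constant (the interfacial polarization/charging response);
* i.i.d. Gaussian measurement noise per sample.

Vintage (production-year) classes modulate the conductance and the transient
time constant per electrode by fixed multiplicative factors ``1 + delta*u``
with ``u ~ Uniform(-1, 1)`` drawn once per (electrode, class) from a dedicated
seed.  ``delta`` is the separability dial: ``delta=0`` makes all classes
statistically identical; the default ``delta=0.2`` with 0.05 mA noise gives
near-separable classes, while ``delta≈0.02`` produces the partial overlap seen
between adjacent vintages in real measurements.  Baselines are deliberately
class-invariant so that offset-insensitivity of the downstream pipeline is a
testable claim.

This is not an electrochemistry model: there is no Faradaic peak, drift,
fouling or temperature term, and no quantitative fidelity to any instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .waveform import ExcitationWaveform, WaveformSpec, build_waveform

__all__ = [
    "ELECTRODE_NAMES",
    "ElectrodeParams",
    "VintageEffect",
    "SimulationConfig",
    "SampleRecord",
    "Dataset",
    "default_electrode_params",
    "default_config",
    "class_multipliers",
    "simulate_sample",
    "simulate_dataset",
]

#: Fixed electrode order used for horizontal concatenation throughout.
ELECTRODE_NAMES = ("Ag", "Au", "Ti", "Pd", "Pt", "W")

#: Five consecutive production years (the vintage classes).
DEFAULT_CLASSES = (2016, 2017, 2018, 2019, 2020)


@dataclass(frozen=True)
class ElectrodeParams:
    """Per-electrode signal-model parameters (currents in mA, voltages in V).

    ``baseline`` is the class-invariant offset; ``conductance`` (mA/V) scales
    the ohmic term; ``transient_amplitude`` (mA/V) and ``transient_tau`` (s)
    shape the step response at plateau edges; ``noise_sd`` (mA) is the
    per-sample Gaussian noise level.
    """

    name: str
    baseline: float = 28.0
    conductance: float = 5.0
    transient_amplitude: float = 2.0
    transient_tau: float = 0.02
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.conductance < 0:
            raise ValueError(f"conductance must be >= 0, got {self.conductance}")
        if self.transient_tau <= 0:
            raise ValueError(f"transient_tau must be > 0, got {self.transient_tau}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass(frozen=True)
class VintageEffect:
    """Class-effect specification.

    Each (electrode, class) pair gets one multiplier on conductance and one on
    transient_tau, drawn as ``1 + delta*u`` with ``u ~ Uniform(-1, 1)`` from a
    generator seeded by ``(modulation_seed, electrode_index, class_index)`` —
    a deterministic function of those three integers.  ``delta=0`` gives
    multipliers exactly 1.
    """

    delta: float = 0.2
    modulation_seed: int = 20160

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")


@dataclass(frozen=True)
class SimulationConfig:
    classes: tuple[int, ...] = DEFAULT_CLASSES
    n_per_class: int = 100
    electrodes: tuple[ElectrodeParams, ...] = ()
    effect: VintageEffect = field(default_factory=VintageEffect)
    noise_seed: int = 1234
    waveform_spec: WaveformSpec = field(default_factory=WaveformSpec)

    def __post_init__(self) -> None:
        if not self.electrodes:
            object.__setattr__(self, "electrodes", tuple(default_electrode_params()))
        if len(self.electrodes) != 6:
            raise ValueError(f"exactly 6 electrodes required, got {len(self.electrodes)}")
        if self.n_per_class < 1:
            raise ValueError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if not self.classes:
            raise ValueError("classes must be non-empty")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError(f"class labels must be unique, got {self.classes}")


@dataclass(frozen=True)
class SampleRecord:
    """One measured specimen: label plus a 6 x n_samples current matrix (mA)."""

    label: int
    currents: np.ndarray

    def __post_init__(self) -> None:
        if self.currents.ndim != 2 or self.currents.shape[0] != 6:
            raise ValueError(f"currents must be 6 x n_samples, got {self.currents.shape}")


@dataclass(frozen=True)
class Dataset:
    """A labelled collection of records plus the concatenated design matrix.

    ``X_concat`` stacks each record's channels horizontally in the fixed
    electrode order (Ag, Au, Ti, Pd, Pt, W): row = [Ag 0..L-1, Au 0..L-1, ...].
    """

    records: tuple[SampleRecord, ...]
    electrode_names: tuple[str, ...] = ELECTRODE_NAMES
    waveform_spec: WaveformSpec = field(default_factory=WaveformSpec)

    @property
    def X_concat(self) -> np.ndarray:
        return np.stack([r.currents.reshape(-1) for r in self.records])

    @property
    def y(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    @property
    def n_samples_per_electrode(self) -> int:
        return self.records[0].currents.shape[1]

    def __len__(self) -> int:
        return len(self.records)

    def with_offset(self, offset_mA: float) -> "Dataset":
        """A copy with a constant current offset added to every raw sample."""
        return Dataset(
            records=tuple(
                SampleRecord(r.label, r.currents + offset_mA) for r in self.records
            ),
            electrode_names=self.electrode_names,
            waveform_spec=self.waveform_spec,
        )


def default_electrode_params(noise_sd: float = 0.05) -> list[ElectrodeParams]:
    """The six default electrode parameter sets.

    All share the 28 mA baseline; conductance, transient amplitude and time
    constant are distinct per metal so the channels are distinguishable.  The
    values are package defaults chosen to give currents in the ~21-35 mA range
    over the ±1 V ladder with transients decaying well within a 0.1 s plateau.
    """
    table = {
        # name: (conductance mA/V, transient_amplitude mA/V, tau s)
        "Ag": (5.0, 2.0, 0.020),
        "Au": (6.5, 1.5, 0.030),
        "Ti": (3.5, 3.0, 0.015),
        "Pd": (5.5, 2.5, 0.025),
        "Pt": (7.0, 1.8, 0.040),
        "W": (4.2, 2.8, 0.018),
    }
    return [
        ElectrodeParams(
            name=name,
            baseline=28.0,
            conductance=g,
            transient_amplitude=a,
            transient_tau=tau,
            noise_sd=noise_sd,
        )
        for name, (g, a, tau) in table.items()
    ]


def default_config(
    delta: float = 0.2,
    noise_sd: float = 0.05,
    n_per_class: int = 100,
    noise_seed: int = 1234,
    modulation_seed: int = 20160,
) -> SimulationConfig:
    """The study-design configuration: 5 vintages x 100 samples, 6 electrodes."""
    return SimulationConfig(
        classes=DEFAULT_CLASSES,
        n_per_class=n_per_class,
        electrodes=tuple(default_electrode_params(noise_sd=noise_sd)),
        effect=VintageEffect(delta=delta, modulation_seed=modulation_seed),
        noise_seed=noise_seed,
    )


def class_multipliers(
    effect: VintageEffect, electrode_index: int, class_index: int
) -> tuple[float, float]:
    """(conductance multiplier, tau multiplier) for one (electrode, class)."""
    rng = np.random.default_rng(
        [int(effect.modulation_seed), int(electrode_index), int(class_index)]
    )
    u = rng.uniform(-1.0, 1.0, size=2)
    return 1.0 + effect.delta * u[0], 1.0 + effect.delta * u[1]


def _noiseless_template(
    cfg: SimulationConfig, class_index: int, w: ExcitationWaveform
) -> np.ndarray:
    """Deterministic 6 x n_samples response for one class (no noise).

    Per electrode e and plateau p with level V_p and previous level V_{p-1}
    (V_{-1} = 0), at in-plateau time t from the plateau start:

        I(t) = baseline_e + g_ec * V_p
               + a_e * (V_p - V_{p-1}) * exp(-t / tau_ec)
    """
    levels = w.plateau_levels
    prev = np.concatenate(([0.0], levels[:-1]))
    dt = w.spec.sampling_interval
    t = np.arange(w.samples_per_plateau) * dt  # time from plateau start
    out = np.empty((6, w.n_samples))
    for e, params in enumerate(cfg.electrodes):
        mg, mtau = class_multipliers(cfg.effect, e, class_index)
        g = params.conductance * mg
        tau = params.transient_tau * mtau
        ohmic = np.repeat(params.baseline + g * levels, w.samples_per_plateau)
        step = (params.transient_amplitude * (levels - prev))[:, None] * np.exp(
            -t[None, :] / tau
        )
        out[e] = ohmic + step.reshape(-1)
    return out


def simulate_sample(
    cfg: SimulationConfig, class_label: int, rng: np.random.Generator
) -> SampleRecord:
    """One synthetic specimen of the given class; noise drawn from ``rng``."""
    try:
        class_index = cfg.classes.index(class_label)
    except ValueError:
        raise KeyError(
            f"unknown class label {class_label!r}; configured classes: {cfg.classes}"
        ) from None
    w = build_waveform(cfg.waveform_spec)
    template = _noiseless_template(cfg, class_index, w)
    sds = np.array([p.noise_sd for p in cfg.electrodes])
    noise = rng.normal(0.0, 1.0, size=template.shape) * sds[:, None]
    return SampleRecord(label=class_label, currents=template + noise)


def simulate_dataset(cfg: SimulationConfig) -> Dataset:
    """The full labelled dataset: classes in configured order, ``n_per_class``
    records each, with a single noise stream seeded by ``cfg.noise_seed``.

    Generation order (class-major, record-minor) and both seed streams fully
    determine the output, byte for byte.
    """
    w = build_waveform(cfg.waveform_spec)
    rng = np.random.default_rng(int(cfg.noise_seed))
    sds = np.array([p.noise_sd for p in cfg.electrodes])
    records: list[SampleRecord] = []
    for ci, label in enumerate(cfg.classes):
        template = _noiseless_template(cfg, ci, w)
        noise = rng.normal(0.0, 1.0, size=(cfg.n_per_class,) + template.shape)
        noise *= sds[None, :, None]
        for k in range(cfg.n_per_class):
            records.append(SampleRecord(label=label, currents=template + noise[k]))
    return Dataset(
        records=tuple(records),
        electrode_names=tuple(p.name for p in cfg.electrodes),
        waveform_spec=cfg.waveform_spec,
    )
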