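"""Experiment configuration: defaults, YAML loading, validation.

Every parameter that affects results is explicit here and lands in the run
manifest; loading materializes all defaults so there are no silent ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classical import RFConfig, SVMConfig
from .cnn import CNNConfig
from .features import FEATURE_KINDS
from .simulate import SimulationConfig, VintageEffect, default_config
from .waveform import WaveformSpec

__all__ = ["PipelineConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration; message names the field."""


@dataclass(frozen=True)
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=default_config)
    normalization_scope: str = "train_only"
    feature_kinds: tuple[str, ...] = FEATURE_KINDS
    svm: SVMConfig = field(default_factory=SVMConfig)
    rf: RFConfig = field(default_factory=RFConfig)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    cnn_epochs: int | None = None  # override of cnn.epochs for desk-scale runs
    split_fraction: float = 0.8
    split_seed: int = 42
    model_seed: int = 42
    skip_cnn: bool = False
    output_dir: str = "etongue_results"
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ConfigError(f"split_fraction must be in (0, 1), got {self.split_fraction}")
        bad = set(self.feature_kinds) - set(FEATURE_KINDS)
        if bad:
            raise ConfigError(f"feature_kinds contains unknown kinds: {sorted(bad)}")
        if self.normalization_scope not in ("train_only", "all"):
            raise ConfigError(
                f"normalization_scope must be 'train_only' or 'all', "
                f"got {self.normalization_scope!r}"
            )
        if self.cnn.n_classes != len(self.simulation.classes):
            raise ConfigError(
                f"cnn.n_classes = {self.cnn.n_classes} inconsistent with "
                f"{len(self.simulation.classes)} simulation classes"
            )

    @property
    def effective_cnn_epochs(self) -> int:
        return self.cnn_epochs if self.cnn_epochs is not None else self.cnn.epochs

    def seeds(self) -> dict:
        """All seeds affecting results, for the manifest."""
        return {
            "noise_seed": self.simulation.noise_seed,
            "modulation_seed": self.simulation.effect.modulation_seed,
            "split_seed": self.split_seed,
            "model_seed": self.model_seed,
            "cnn_seed": self.cnn.seed,
        }


def _build(payload: dict) -> PipelineConfig:
    try:
        sim_kw = dict(payload.get("simulation", {}))
        wf = WaveformSpec(**sim_kw.pop("waveform_spec", {}))
        effect = VintageEffect(**sim_kw.pop("effect", {}))
        noise_sd = sim_kw.pop("noise_sd", 0.05)
        base = default_config(
            delta=effect.delta,
            noise_sd=noise_sd,
            n_per_class=sim_kw.pop("n_per_class", 100),
            noise_seed=sim_kw.pop("noise_seed", 1234),
            modulation_seed=effect.modulation_seed,
        )
        if "classes" in sim_kw:
            base = SimulationConfig(
                classes=tuple(sim_kw.pop("classes")),
                n_per_class=base.n_per_class,
                electrodes=base.electrodes,
                effect=base.effect,
                noise_seed=base.noise_seed,
                waveform_spec=wf,
            )
        if sim_kw:
            raise ConfigError(f"simulation: unknown fields {sorted(sim_kw)}")
        cnn_kw = dict(payload.get("cnn", {}))
        cnn = CNNConfig(
            n_classes=len(base.classes),
            **{k: v for k, v in cnn_kw.items() if k != "n_classes"},
        )
        return PipelineConfig(
            simulation=base,
            normalization_scope=payload.get("normalization_scope", "train_only"),
            feature_kinds=tuple(payload.get("feature_kinds", FEATURE_KINDS)),
            svm=SVMConfig(**payload.get("svm", {})),
            rf=RFConfig(**payload.get("rf", {})),
            cnn=cnn,
            cnn_epochs=payload.get("cnn_epochs"),
            split_fraction=payload.get("split_fraction", 0.8),
            split_seed=payload.get("split_seed", 42),
            model_seed=payload.get("model_seed", 42),
            skip_cnn=payload.get("skip_cnn", False),
            output_dir=payload.get("output_dir", "etongue_results"),
            verbosity=payload.get("verbosity", "INFO"),
        )
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path=None) -> PipelineConfig:
    """Load a pipeline config from YAML; ``None`` gives the full default."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    try:
        payload = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if payload is None:
        payload = {}
    if not isinstance(payload, dict):
        raise ConfigError(f"config root must be a mapping, got {type(payload).__name__}")
    return _build(payload)
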