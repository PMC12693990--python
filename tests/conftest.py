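import numpy as np
import pytest

from etongue.simulate import SimulationConfig, VintageEffect, default_electrode_params, simulate_dataset
from etongue.waveform import WaveformSpec, build_waveform


@pytest.fixture(scope="session")
def default_waveform():
    return build_waveform(WaveformSpec())


@pytest.fixture(scope="session")
def small_config():
    """3 vintages x 8 samples, well-separated classes, low noise."""
    return SimulationConfig(
        classes=(2018, 2019, 2020),
        n_per_class=8,
        electrodes=tuple(default_electrode_params(noise_sd=0.02)),
        effect=VintageEffect(delta=0.3, modulation_seed=7),
        noise_seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_X(small_dataset):
    # cache: X_concat is assembled on access
    return small_dataset.X_concat
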