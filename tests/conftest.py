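import numpy as np
import pytest

from flexdecode.core import Epoch, SpikeRaster, StimulusProtocol
from flexdecode.simulate import GeneratorConfig, sample_tuning


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Small, fast ensemble used across module tests."""
    return GeneratorConfig(
        n_neurons=20,
        n_trials=5,
        odors=("hex", "2oct"),
        baseline_rate_mean_hz=3.0,
        baseline_rate_sd_hz=0.5,
        on_amplitude_hz=30.0,
        seed=7,
    )


@pytest.fixture
def default_config():
    return GeneratorConfig(seed=11)


@pytest.fixture
def solitary_protocol():
    return StimulusProtocol(
        epochs=(Epoch("hex", 0.0, 4.0),), trial_count=5, alignment="hex"
    )


@pytest.fixture
def sequence_protocol_hex():
    return StimulusProtocol(
        epochs=(Epoch("2oct", -4.5, -0.5), Epoch("hex", 0.0, 4.0)),
        trial_count=5,
        alignment="hex",
    )


def make_raster(spike_map, n_trials=1):
    """Raster from {(neuron, trial): [times]} with ids inferred."""
    ids = sorted({nid for nid, _ in spike_map})
    return SpikeRaster(
        neuron_ids=tuple(ids),
        trial_count=n_trials,
        spikes={k: np.asarray(v, dtype=float) for k, v in spike_map.items()},
    )


@pytest.fixture
def small_ground_truth(small_config):
    return sample_tuning(small_config)
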