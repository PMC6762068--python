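import numpy as np
import pytest

from valvemonitor import SimulationConfig, generate_recording, preprocess_recording


@pytest.fixture
def quiet_config():
    """Noise-free, leak-free default configuration."""
    return SimulationConfig(leak_area=0.0, noise_sd=0.0, seed=0)


@pytest.fixture
def baseline_recording():
    """A typical noisy baseline recording (1000 samples at 60 Hz)."""
    return generate_recording(SimulationConfig(seed=7, scenario="baseline"))


@pytest.fixture
def baseline_features(baseline_recording):
    return preprocess_recording(baseline_recording)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_cloud(rng, l, d=2):
    """Small blob-shaped training set for SVM tests."""
    centers = rng.normal(0.0, 2.0, size=(3, d))
    assignments = rng.integers(0, 3, size=l)
    return centers[assignments] + rng.normal(0.0, 0.6, size=(l, d))
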