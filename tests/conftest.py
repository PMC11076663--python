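import dataclasses

import numpy as np
import pytest

from fnirspipe.synth import SimulationConfig, generate_block_design, simulate_recording


@pytest.fixture(scope="session")
def finger_config():
    return SimulationConfig.for_paradigm("finger_tapping")


@pytest.fixture(scope="session")
def finger_markers(finger_config):
    return generate_block_design(finger_config)


@pytest.fixture(scope="session")
def noisy_recording(finger_config):
    """One default-noise finger-tapping session, seed 7."""
    cfg = dataclasses.replace(finger_config, seed=7)
    return cfg, *simulate_recording(cfg)


@pytest.fixture(scope="session")
def clean_recording(finger_config):
    """Noise-free, artifact-free session: pipeline should be near-exact."""
    cfg = finger_config.without_noise()
    return cfg, *simulate_recording(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
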