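import logging

import numpy as np
import pytest

from gazeflow.synthetic import SimConfig, simulate_gaze_session

logging.getLogger("gazeflow").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def base_config() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def gaze_session(base_config):
    """One rasterized 300-s session shared across classifier tests."""
    return simulate_gaze_session(base_config, participant=0, session=0, seed=123)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
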