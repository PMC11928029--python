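"""Shared fixtures and deterministic hypothesis settings."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aif_bandit.generative_model import init_model
from aif_bandit.task_environment import TaskConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def config():
    return TaskConfig()


@pytest.fixture
def short_config():
    return TaskConfig(n_trials=10, seed=0)


@pytest.fixture
def model(config):
    return init_model(config=config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
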