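import numpy as np
import pytest
from hypothesis import settings

from dmdibl import ModelParams, TaskConfig

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_task():
    """Short sheets for fast property checks."""
    return TaskConfig(n_items=30, time_budget=20.0)


@pytest.fixture
def quiet_params():
    """Deterministic parameters (no noise) in the fitted range."""
    return ModelParams(F=1.0, f=0.005, d=4.0, s=0.0)
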