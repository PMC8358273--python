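import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from colsync.dynamics import SimulationConfig

settings.register_profile(
    "colsync",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("colsync")


@pytest.fixture
def fast_sim() -> SimulationConfig:
    """Reduced-replicate simulation settings for quick tests."""
    return SimulationConfig(n_reps=5, master_seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
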