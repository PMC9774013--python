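import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def sinusoid():
    """Noiseless sinusoid with period incommensurate with the window."""
    t = np.arange(1, 201, dtype=float)
    return np.sin(2.0 * np.pi * t / 17.0)


@pytest.fixture(scope="session")
def two_sinusoid_signal():
    """Noiseless low-rank signal the SSA trend model reproduces exactly."""
    t = np.arange(1, 601, dtype=float)
    return 100.0 + 5.0 * np.sin(2.0 * np.pi * t / 50.0) + 3.0 * np.sin(2.0 * np.pi * t / 23.0)
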