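import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from photoniche import OpticalModel, SimulationConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def kd40() -> OpticalModel:
    """The study-site water column: K_d = 0.40 m^-1, relative units."""
    return OpticalModel(kd=0.40, e0=100.0)


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
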