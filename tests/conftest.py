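import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cholspec as cs

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return cs.WavelengthGrid()


@pytest.fixture(scope="session")
def settings_default():
    return cs.RetrievalSettings()


@pytest.fixture(scope="session")
def led():
    return cs.LEDModel()


@pytest.fixture(scope="session")
def chromogen():
    return cs.ChromogenModel()


@pytest.fixture(scope="session")
def profile(grid, chromogen):
    return chromogen.profile(grid.wavelengths())


@pytest.fixture(scope="session")
def incident(grid, led):
    return cs.resample_to_integer_grid(led.nominal_spectrum(), grid)


@pytest.fixture
def noiseless():
    return cs.NoiseModel(jitter=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
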