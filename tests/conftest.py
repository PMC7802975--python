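import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from edsim.arrivals import build_profile, default_triage_fractions, realize_arrivals
from edsim.model import default_parameters

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def fractions():
    return default_triage_fractions()


@pytest.fixture(scope="session")
def uncongested_series():
    return realize_arrivals(build_profile("uncongested"))


@pytest.fixture(scope="session")
def peak_series():
    return realize_arrivals(build_profile("peak"))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
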