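import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fuzzrisk.datasets import load_fixture
from fuzzrisk.fmea import default_scales

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scales():
    return default_scales()


@pytest.fixture(scope="session")
def index_matrix():
    """The packaged 20 x 3 per-method benefit-index matrix."""
    return load_fixture("method_indices")


@pytest.fixture(scope="session")
def hybrid_expected():
    return load_fixture("hybrid_expected")


@pytest.fixture(scope="session")
def transplant_register():
    return load_fixture("transplant_register")


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
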