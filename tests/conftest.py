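import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sitematch import load_preset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def coarse_rep():
    return load_preset("coarse_ca")


@pytest.fixture(scope="session")
def blosum_rep():
    return load_preset("ca_centroid_blosum")


@pytest.fixture(scope="session")
def chemgroups_rep():
    return load_preset("chemgroups")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
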