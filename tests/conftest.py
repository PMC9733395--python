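import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vizreach.protocol import build_protocol

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def exp1_protocol():
    return build_protocol("exp1")


@pytest.fixture(scope="session")
def exp2_protocol():
    return build_protocol("exp2")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
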