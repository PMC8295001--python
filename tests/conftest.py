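import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fcmseg.phantom import PhantomSpec, generate_phantom

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_phantom():
    """64x64 4-class concentric phantom shared across tests."""
    return generate_phantom(PhantomSpec(shape=(64, 64), seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
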