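import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gutmet import synth
from gutmet.encoders import FallbackECEncoder, FallbackMetaboliteEncoder

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ec_encoder():
    return FallbackECEncoder()


@pytest.fixture(scope="session")
def met_encoder():
    return FallbackMetaboliteEncoder()


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world shared by unit tests."""
    return synth.generate_world(
        synth.WorldConfig(n_bacteria=20, n_metabolites=15, seed=11)
    )


@pytest.fixture(scope="session")
def default_world():
    """A world at the generator's default study conditions."""
    return synth.generate_world(synth.WorldConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
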