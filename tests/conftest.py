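import numpy as np
import pytest
from hypothesis import settings

from probass import FixtureConfig, generate_fixture
from probass.model import BoostParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

SMALL_CONFIG = FixtureConfig(
    n_res_a=20, n_res_b=15, n_single=170, n_double=30,
    informative_dims=10, seed=11,
)


@pytest.fixture(scope="session")
def small_fixture():
    """200-mutation toy dataset; cheap enough for structural protocol tests."""
    return generate_fixture(SMALL_CONFIG)


@pytest.fixture(scope="session")
def full_fixture():
    """The full study-condition fixture: 2000 mutations, 20 informative dims."""
    return generate_fixture(FixtureConfig())


@pytest.fixture(scope="session")
def fast_params():
    """Small ensemble for tests that check protocol structure, not accuracy."""
    return BoostParams(n_estimators=40, learning_rate=0.2, min_child_samples=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
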