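import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wmlpatterns.simulate import GeneratorConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def cohort_seed1(default_config):
    """One default synthetic cohort, shared across tests that only read it."""
    return generate_cohort(default_config, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
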