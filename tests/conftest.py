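import pytest
from hypothesis import HealthCheck, settings

import dppsim

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> dppsim.ParameterSet:
    return dppsim.ParameterSet.default()


@pytest.fixture(scope="session")
def small_cohort(params):
    """500 individuals, enough for fast engine runs."""
    return dppsim.sample_cohort(params.population, seed=42, n=500)


@pytest.fixture(scope="session")
def large_cohort(params):
    """10^4 individuals for distributional checks."""
    return dppsim.sample_cohort(params.population, seed=7, n=10_000)
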