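import pytest
from hypothesis import HealthCheck, settings

from remotecm.pilot import pilot_cohort, pilot_covariates
from remotecm.protocol import default_plan

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def plan():
    return default_plan()


@pytest.fixture(scope="session")
def pilot_events(plan):
    return pilot_cohort(plan)


@pytest.fixture(scope="session")
def pilot_cov():
    return pilot_covariates()
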