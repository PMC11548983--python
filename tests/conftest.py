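import pytest
from hypothesis import HealthCheck, settings

import fuzzyhaem as fh

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return fh.default_config()


@pytest.fixture(scope="session")
def rulebase():
    return fh.default_rulebase()


@pytest.fixture(scope="session")
def adult_female():
    return fh.DemographicGroup(fh.Gender.G2, fh.AgeGroup.A5)


@pytest.fixture(scope="session")
def adult_male():
    return fh.DemographicGroup(fh.Gender.G1, fh.AgeGroup.A5)


@pytest.fixture(scope="session")
def worked_cases():
    return fh.table3_fixture()


@pytest.fixture(scope="session")
def worked_predictions(worked_cases, config, rulebase):
    """Ranked engine output for the 22 packaged worked cases."""
    return [
        fh.rank_diagnoses(fh.diagnose(case.labeled.record, config, rulebase))
        for case in worked_cases
    ]
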