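import pytest
from hypothesis import HealthCheck, settings

import methpanel as mp

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cohort_fixtures():
    """The six embedded published count fixtures."""
    return mp.builtin_cohort_fixtures()


@pytest.fixture(scope="session")
def gac_mshrm(cohort_fixtures):
    return cohort_fixtures["gac-mshrm"]


@pytest.fixture(scope="session")
def luad_mshrm(cohort_fixtures):
    return cohort_fixtures["luad-mshrm"]


@pytest.fixture(scope="session")
def mshrm_sheet(gac_mshrm):
    """178-sample MS-HRM sample sheet (89 tumor/normal pairs)."""
    _, records, _ = gac_mshrm
    return records
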