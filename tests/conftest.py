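import pytest
from hypothesis import HealthCheck, settings

from crosswise import make_design, study_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def design24():
    """The study design: innocuous-name prevalence 24%."""
    return make_design(0.24)


@pytest.fixture(scope="session")
def fixture_survey():
    """One canonical 75x20 study fixture, with its truth sidecar."""
    return study_fixture(seed=1)
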