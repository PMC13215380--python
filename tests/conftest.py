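import pytest
from hypothesis import HealthCheck, settings

from pbtampon import ModelParams, ReleaseSchedule

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def baseline_schedule() -> ReleaseSchedule:
    return ReleaseSchedule()
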