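import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from wearcopd.config import CohortConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig()


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """Two patients over one week: enough to exercise every stage quickly."""
    return CohortConfig(n_patients=2, study_days=7, seed=42)


@pytest.fixture(scope="session")
def study_start(default_config) -> dt.date:
    return dt.date.fromisoformat(default_config.start_date)
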