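import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tracewell as tw

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-user cohort with message and usage streams, shared read-only."""
    cfg = tw.CohortConfig(n_users=40, seed=11, message_rate=60,
                          usage_sessions_per_week=40)
    return cfg, tw.generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
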