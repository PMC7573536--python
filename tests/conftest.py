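import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fcnf import FeedbackConfig, build_run_schedule

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def exp12_schedule():
    """Standard design: 20-volume fixation, 7 alternating 20/20 pairs."""
    return build_run_schedule(20, 7, 20, 20, "fcnf")


@pytest.fixture(scope="session")
def exp3_schedule():
    """Extended design: 40-volume feedback blocks, 5 pairs."""
    return build_run_schedule(20, 5, 40, 20, "nonf")


@pytest.fixture(scope="session")
def weighted_config():
    return FeedbackConfig("weighted_negative")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
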