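import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def short_recording():
    """120 s synthetic recording with ground truth (session-scoped for speed)."""
    from vigilscore import StateSchedule, synth_recording

    sched = StateSchedule(
        [("a1", 30.0), ("a3", 15.0), ("nREM1", 45.0), ("REM", 15.0), ("nREM2", 15.0)]
    )
    rec, truth = synth_recording(sched, seed=11)
    return rec, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
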