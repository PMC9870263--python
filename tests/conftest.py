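import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def gait_session():
    """One noise-free participant session with a zero injected lag."""
    from rollgait import simulate_cohort

    rec = simulate_cohort(n_participants=1, seed=7, noise=False, max_lag_samples=0)[0]
    return rec.sessions["T1"]


@pytest.fixture
def noisy_cohort():
    """Small noisy cohort shared by the slower integration tests."""
    from rollgait import simulate_cohort

    return simulate_cohort(n_participants=4, seed=13, noise=True)
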