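import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-participant, one-session cohort used by pipeline round-trip tests."""
    from sjtbw import CohortConfig, simulate_cohort

    config = CohortConfig(n_participants=2, n_sessions_per_condition=1, seed=7)
    return simulate_cohort(config)
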