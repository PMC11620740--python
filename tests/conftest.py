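import numpy as np
import pytest

from varicount import SimulationConfig, fixed_n_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """A clean fixed-n cohort table (n=1000, 20 animals, 1e5 events)."""
    return fixed_n_cohort(
        SimulationConfig(n=1000, n_animals=20, recorded_events=100_000, seed=0)
    )
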