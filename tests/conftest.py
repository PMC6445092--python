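import numpy as np
import pytest

from percue import protocol


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort_trials():
    """Paired 6-subject cohort shared by analysis/protocol tests."""
    config = protocol.SimulationConfig(n_subjects=6)
    return protocol.simulate_cohort(config, seed=7)
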