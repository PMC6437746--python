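import numpy as np
import pytest

from methylnet.synthetic import CohortSpec, simulate_discovery_cohort


@pytest.fixture(scope="session")
def discovery_cohort():
    """Default-scale discovery cohort (841 sites, 6 vs 6), shared across tests."""
    return simulate_discovery_cohort(CohortSpec(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
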