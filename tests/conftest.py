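import numpy as np
import pytest

from graftmobile import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return SimulationConfig(
        error_rate=0.01,
        homograft_depth=200,
        heterograft_depth=200,
        mobile_reads=20,
        snps_per_transcript=2,
        replicates=3,
        n_transcripts=6,
        seed=7,
    )


@pytest.fixture
def small_cohort(small_config):
    return simulate_cohort(small_config)
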