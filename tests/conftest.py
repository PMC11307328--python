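import numpy as np
import pytest

from crispr_memory.config import Parameters
from crispr_memory.simulate import (
    SimulationConfig,
    emit_observed_dataset,
    generate_community,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_subjects=2, n_samples_per_subject=8, n_lineages_per_subject=2,
        n_mge=12, mge_len=600, gain_rate=0.6, loss_rate=0.02,
        contig_flank=100, rng_seed=42,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_community(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    return emit_observed_dataset(small_truth)


@pytest.fixture(scope="session")
def fast_params():
    return Parameters(rng_seed=42, n_bootstraps=200, community_trials=20)
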