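import numpy as np
import pytest

from nlmsem import (
    PopulationConfig,
    simulate_dataset,
    stats_from_dataset,
)


@pytest.fixture(scope="session")
def config_wibi():
    """Interaction effects at both levels, correlated predictors."""
    return PopulationConfig(
        n_groups=150, group_size=20, phi21=0.30,
        gamma3_within=0.20, gamma3_between=0.20, seed=424242,
    )


@pytest.fixture(scope="session")
def dataset_wibi(config_wibi):
    return simulate_dataset(config_wibi, keep_latent=True)


@pytest.fixture(scope="session")
def stats_wibi(dataset_wibi):
    return stats_from_dataset(dataset_wibi)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(97531)
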