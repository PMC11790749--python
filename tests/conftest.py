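import numpy as np
import pytest

import biftwin as bt

from helpers import make_cp, make_ip, small_structure


@pytest.fixture(scope="session")
def structure20():
    return bt.conners_structure()


@pytest.fixture(scope="session")
def small4():
    return small_structure()


@pytest.fixture(scope="session")
def published_loadings():
    return bt.load_published_loadings()


@pytest.fixture(scope="session")
def cp_params_small(small4):
    return make_cp(small4)


@pytest.fixture(scope="session")
def ip_params_small(small4):
    return make_ip(small4)


@pytest.fixture(scope="session")
def small_dataset(cp_params_small):
    """Complete-data CP AE sample reused across read-only tests."""
    cfg = bt.SimulationConfig(n_MZ=300, n_DZ=300, params=cp_params_small, seed=7)
    return bt.simulate_twins(cfg)


@pytest.fixture(scope="session")
def small_dataset_missing(cp_params_small):
    cfg = bt.SimulationConfig(n_MZ=150, n_DZ=150, params=cp_params_small,
                              seed=8, missing_rate=0.15)
    return bt.simulate_twins(cfg)


@pytest.fixture
def toy_dataset(small4):
    items = np.zeros((2, 2, 4))
    items[0, 0] = [0, 1, 2, 3]
    items[1, 1] = [3, 2, 1, 0]
    covs = np.zeros((2, 2, 3))
    covs[:, :, 0] = 22.0
    return bt.TwinPairDataset(
        pair_ids=np.array(["a", "b"], dtype=object),
        zygosity=np.array(["MZ", "DZ"], dtype=object),
        items=items,
        covariates=covs,
    )
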