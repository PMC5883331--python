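import numpy as np
import pytest

import transcortex as tx


@pytest.fixture(scope="session")
def atlas60():
    """A 60-parcel-per-hemisphere atlas shared across tests."""
    return tx.make_atlas(60, seed=1)


@pytest.fixture(scope="session")
def reduced_dataset():
    """A down-scaled synthetic dataset (60 parcels, 4 planted modules)."""
    return tx.simulate_dataset(tx.reduced_config(seed=3))


@pytest.fixture(scope="session")
def reduced_regional(reduced_dataset):
    from transcortex.pipeline import map_expression

    regional, info = map_expression(reduced_dataset)
    return regional


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
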