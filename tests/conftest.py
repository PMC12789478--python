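import numpy as np
import pytest

import gutswitch as gs


@pytest.fixture(scope="session")
def default_model():
    return gs.build_default_community()


@pytest.fixture(scope="session")
def bistable_model():
    return gs.minimal_bistable_fixture()


@pytest.fixture(scope="session")
def bh_batch_data():
    """Noisy Bh monoculture batch dataset plus its generating truth."""
    return gs.batch_fixture(["bh"], seed=1)


@pytest.fixture(scope="session")
def ri_noise_free_data():
    """Noise-free Ri monoculture dataset (calibration self-consistency)."""
    return gs.batch_fixture(["ri"], seed=1, cell_noise_cv=0.0,
                            met_noise_sd=0.0, ph_noise_sd=0.0, n_replicates=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1)
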