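import numpy as np
import pytest

from mlsam.datagen import generate_mlsem, generate_pn
from mlsam.params import default_params


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def within_ds():
    """Moderately sized within-interaction dataset shared across tests."""
    return generate_mlsem(design="within", n2=60, n1=25, seed=314159)


@pytest.fixture(scope="session")
def big_within_ds():
    """Large dataset for consistency checks (kept to one generation)."""
    return generate_mlsem(design="within", n2=400, n1=30, seed=271828)


@pytest.fixture(scope="session")
def pn_ds():
    return generate_pn(n2_t=40, n1_t=15, seed=161803)


@pytest.fixture(scope="session")
def big_pn_ds():
    return generate_pn(n2_t=600, n1_t=30, seed=662607)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
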