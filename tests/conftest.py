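import numpy as np
import pytest

from entrotest import CountTable, load_gss, gss_collapsed_1998


@pytest.fixture(scope="session")
def gss():
    """The packaged survey contingency table, one CountTable per year."""
    return load_gss()


@pytest.fixture(scope="session")
def gss_1998(gss):
    return gss["1998"]


@pytest.fixture(scope="session")
def gss_2018(gss):
    return gss["2018"]


@pytest.fixture(scope="session")
def gss_1998_collapsed():
    return gss_collapsed_1998()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_simplex(rng: np.random.Generator, k: int, min_p: float = 1e-3) -> np.ndarray:
    """A strictly positive random probability vector."""
    x = rng.dirichlet(np.ones(k)) * (1 - k * min_p) + min_p
    return x / x.sum()
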