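import numpy as np
import pytest

from adap.model_core import SiteDataset


def random_site(rng, n=60, p=4, beta=None, site_id="s", rho=0.0):
    """A small random logistic dataset with an intercept column."""
    z = rng.standard_normal((n, p - 1))
    if rho:
        g = rng.standard_normal((n, 1))
        z = np.sqrt(rho) * g + np.sqrt(1 - rho) * z
    X = np.hstack([np.ones((n, 1)), z])
    if beta is None:
        beta = np.zeros(p)
        beta[0] = -0.3
        beta[1 : min(3, p)] = 0.8
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-X @ beta))).astype(float)
    if y.min() == y.max():  # ensure both classes for fitting
        y[0], y[1] = 0.0, 1.0
    return SiteDataset(X, y, site_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20260)


@pytest.fixture
def toy_ds():
    """Two rows, x = (1, 0.5) and (1, -0.5), y = (1, 0)."""
    return SiteDataset(np.array([[1.0, 0.5], [1.0, -0.5]]),
                       np.array([1.0, 0.0]), "toy")


@pytest.fixture(scope="session")
def oud_fixture():
    from adap.cli_io import make_oud_fixture

    return make_oud_fixture(seed=7)
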