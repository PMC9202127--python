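import numpy as np
import pytest

from countsel import CohortTable, FamilySpec


def make_count_table(seed, n=300, p=5, beta=None, intercept=0.3, theta=None):
    """Simulate a count table: Poisson if theta is None, else NB."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    b = np.zeros(p)
    if beta is not None:
        b[: len(beta)] = beta
    mu = np.exp(intercept + X @ b)
    if theta is None:
        y = rng.poisson(mu)
    else:
        y = rng.poisson(rng.gamma(theta, mu / theta))
    return CohortTable(X, y, [f"x{i + 1}" for i in range(p)])


@pytest.fixture(scope="session")
def poisson_table():
    return make_count_table(10, beta=[0.5, -0.4])


@pytest.fixture(scope="session")
def negbin_table():
    return make_count_table(11, beta=[0.6, -0.5, 0.4], theta=1.0)


@pytest.fixture(scope="session")
def nb_spec():
    return FamilySpec("negbin")
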