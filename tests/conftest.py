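import numpy as np
import pytest

from sarmix import CohortTable, ModelSpec, ParameterSet
from sarmix import synthetic


@pytest.fixture(scope="session")
def desk_dataset():
    """One desk-scale synthetic dataset (30 days x 8 years, wild preset)."""
    cfg = synthetic.desk_scenario(seed=2024)
    return synthetic.generate_dataset(cfg), cfg


@pytest.fixture(scope="session")
def desk_fit(desk_dataset):
    """A converged fit of the generating spec on the desk dataset."""
    from sarmix import SARModel

    ds, cfg = desk_dataset
    res = SARModel(ds.table, ds.X, cfg.spec).fit(start=cfg.params)
    assert res.converged
    return res


@pytest.fixture
def tiny_table():
    """5 days x 3 years lattice with a few fish."""
    rng = np.random.default_rng(42)
    n = rng.integers(0, 30, size=(5, 3))
    k = rng.binomial(n, 0.2)
    return CohortTable("wild", np.arange(100, 105), np.arange(2000, 2003),
                       n, k)


def dense_ar1_cov(corr: float, scale: float, m: int) -> np.ndarray:
    """Oracle covariance: C_ij = scale^2 corr^|i-j| / (1 - corr^2)."""
    i = np.arange(m)
    return scale**2 * corr ** np.abs(i[:, None] - i[None, :]) / (1 - corr**2)


def dense_field_cov(gamma: float, rho: float, sigma: float,
                    J: int, T: int) -> np.ndarray:
    """Oracle covariance built literally from the transition law:
    Cov(xi_t, xi_{t+d}) = gamma^|d| Sigma / (1 - gamma^2) with
    Sigma[j, j+d] = sigma^2 rho^|d| / (1 - rho^2); year-major ordering."""
    jj = np.arange(J)
    tt = np.arange(T)
    Sigma = sigma**2 * rho ** np.abs(jj[:, None] - jj[None, :]) / (1 - rho**2)
    Rg = gamma ** np.abs(tt[:, None] - tt[None, :]) / (1 - gamma**2)
    return np.kron(Rg, Sigma)
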