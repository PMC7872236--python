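"""Density primitives of the SAR mixed model.

The observation model is binomial on each lattice cell,

    k_jt ~ Binomial(n_jt, s_jt),      s_jt = expit(eta_jt),
    eta_jt = mu + beta . x_t + nu_j + omega_t + xi_jt.

The latent components are stationary Gaussians:

* day effect      nu_j  : AR(1), lag-1 correlation tau, innovation scale
  psi, marginal variance psi^2 / (1 - tau^2);
* year effect  omega_t  : AR(1) with (pi, phi) likewise;
* day-by-year field xi  : separable AR(1) x AR(1).  Within a year the day
  covariance is Sigma[j, j+d] = sigma^2 rho^|d| / (1 - rho^2); across
  years the day-vector evolves as xi_t ~ MVN(gamma xi_{t-1}, Sigma),
  initialised at its stationary law MVN(0, Sigma / (1 - gamma^2)).  The
  marginal cell variance is sigma^2 / ((1 - rho^2)(1 - gamma^2)).

A convenient fact used throughout: with the scaled tridiagonal matrix
M(c) = tridiag(-c; [1, 1+c^2, ..., 1+c^2, 1]) the stationary AR(1)
precision is M(tau)/psi^2, the field precision is the Kronecker product
kron(M(gamma), M(rho))/sigma^2 (year-major ordering), and
det M(c) = 1 - c^2 regardless of dimension.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln

from .params import ParameterSet, RandomEffects

__all__ = [
    "inverse_logit",
    "linear_predictor",
    "eta_surface",
    "ar1_nll",
    "field_nll",
    "binomial_nll",
    "joint_nll",
    "saturated_loglik",
]

LOG2PI = float(np.log(2.0 * np.pi))


def inverse_logit(eta):
    """Overflow-safe logistic function s = exp(eta) / (1 + exp(eta))."""
    return expit(eta)


def _check_ar1(corr: float, scale: float) -> None:
    if not -1.0 < corr < 1.0:
        raise ValueError(f"correlation {corr} must lie strictly in (-1, 1)")
    if not scale > 0:
        raise ValueError(f"scale {scale} must be strictly positive")


def ar1_scaled_precision(corr: float, m: int) -> np.ndarray:
    """The matrix M(corr): AR(1) precision times the squared innovation scale.

    For m == 1 this is the 1x1 matrix [1 - corr^2] (a single stationary
    value has variance scale^2 / (1 - corr^2)).
    """
    if m == 1:
        return np.array([[1.0 - corr**2]])
    M = np.zeros((m, m))
    d = np.full(m, 1.0 + corr**2)
    d[0] = d[-1] = 1.0
    np.fill_diagonal(M, d)
    idx = np.arange(m - 1)
    M[idx, idx + 1] = -corr
    M[idx + 1, idx] = -corr
    return M


def ar1_scaled_precision_dcorr(corr: float, m: int) -> np.ndarray:
    """d M(corr) / d corr."""
    if m == 1:
        return np.array([[-2.0 * corr]])
    D = np.zeros((m, m))
    d = np.full(m, 2.0 * corr)
    d[0] = d[-1] = 0.0
    np.fill_diagonal(D, d)
    idx = np.arange(m - 1)
    D[idx, idx + 1] = -1.0
    D[idx + 1, idx] = -1.0
    return D


def ar1_nll(v: np.ndarray, corr: float, scale: float) -> float:
    """Negative log density of a stationary AR(1) Gaussian vector.

    First element ~ Normal(0, scale^2/(1-corr^2)); transitions
    v_j | v_{j-1} ~ Normal(corr v_{j-1}, scale^2).  Equivalent to the
    dense MVN with covariance C_ij = scale^2 corr^|i-j| / (1 - corr^2).
    """
    _check_ar1(corr, scale)
    v = np.asarray(v, dtype=float)
    m = v.size
    M = ar1_scaled_precision(corr, m)
    quad = float(v @ M @ v) / scale**2
    logdet_Q = np.log1p(-corr**2) - 2.0 * m * np.log(scale)
    return 0.5 * (m * LOG2PI - logdet_Q + quad)


def field_nll(xi: np.ndarray, gamma: float, rho: float, sigma: float) -> float:
    """Negative log density of the separable day-by-year field.

    ``xi`` is (n_days, n_years).  Evaluated through the Kronecker
    structure of the precision, kron(M(gamma), M(rho)) / sigma^2, which
    equals the dense construction from the transition law.
    """
    _check_ar1(gamma, sigma)
    _check_ar1(rho, 1.0)
    xi = np.asarray(xi, dtype=float)
    J, T = xi.shape
    Mr = ar1_scaled_precision(rho, J)
    Mg = ar1_scaled_precision(gamma, T)
    # vec'(Mg (x) Mr) vec = sum(xi * (Mr xi Mg'))
    quad = float(np.sum(xi * (Mr @ xi @ Mg))) / sigma**2
    logdet_Q = (
        T * np.log1p(-rho**2)
        + J * np.log1p(-gamma**2)
        - 2.0 * J * T * np.log(sigma)
    )
    return 0.5 * (J * T * LOG2PI - logdet_Q + quad)


def binomial_nll(n, k, s) -> float:
    """Summed binomial negative log likelihood over lattice cells.

    Cells with n == 0 contribute exactly 0.  Requires 0 < s < 1 wherever
    n > 0.
    """
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    s = np.broadcast_to(np.asarray(s, dtype=float), n.shape)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("need 0 <= k <= n")
    obs = n > 0
    if np.any((s[obs] <= 0) | (s[obs] >= 1)):
        raise ValueError("survival must lie strictly in (0, 1) where n > 0")
    no, ko, so = n[obs], k[obs], s[obs]
    logC = gammaln(no + 1) - gammaln(ko + 1) - gammaln(no - ko + 1)
    return float(-np.sum(logC + ko * np.log(so) + (no - ko) * np.log1p(-so)))


def linear_predictor(
    theta: ParameterSet,
    eps: RandomEffects,
    x_t: np.ndarray,
    j: int,
    t: int,
) -> float:
    """eta_jt for one lattice cell; inactive components contribute zero.

    ``x_t`` holds the active covariate values for year index ``t`` and must
    match ``theta.beta`` in length.
    """
    x_t = np.atleast_1d(np.asarray(x_t, dtype=float))
    if x_t.shape != theta.beta.shape:
        raise ValueError(
            f"covariate vector length {x_t.size} != beta length {theta.beta.size}"
        )
    return float(
        theta.mu + theta.beta @ x_t + eps.nu[j] + eps.omega[t] + eps.xi[j, t]
    )


def eta_surface(
    theta: ParameterSet, eps: RandomEffects, x: np.ndarray
) -> np.ndarray:
    """Full (n_days, n_years) linear-predictor surface.

    ``x`` is the (n_years, n_cov) covariate slice aligned with the lattice
    years.
    """
    x = np.asarray(x, dtype=float).reshape(eps.omega.size, theta.beta.size)
    xb = x @ theta.beta
    return theta.mu + xb[None, :] + eps.nu[:, None] + eps.omega[None, :] + eps.xi


def joint_nll(theta: ParameterSet, eps: RandomEffects, data, X) -> float:
    """Joint negative log likelihood of data and latent effects.

    Sum of the binomial observation term over the lattice plus the active
    latent-process negative log densities.  ``data`` is a
    :class:`~sarmix.cohorts.CohortTable`; ``X`` a
    :class:`~sarmix.covariates.CovariateMatrix` (may be ``None`` when the
    model has no covariates).  The active components are inferred from
    which parameters are set on ``theta``.
    """
    if theta.beta.size:
        x = X.align(data.years, _beta_names(theta, X))
    else:
        x = np.zeros((data.years.size, 0))
    eta = eta_surface(theta, eps, x)
    total = binomial_nll(data.n, data.k, inverse_logit(eta))
    if theta.tau is not None:
        total += ar1_nll(eps.nu, theta.tau, theta.psi)
    if theta.pi is not None:
        total += ar1_nll(eps.omega, theta.pi, theta.phi)
    if theta.rho is not None:
        total += field_nll(eps.xi, theta.gamma, theta.rho, theta.sigma)
    return total


def _beta_names(theta: ParameterSet, X) -> list[str]:
    # Without an explicit spec, covariates are taken as the first columns
    # of X in order; SARModel always passes an aligned slice instead.
    return list(X.names[: theta.beta.size])


def saturated_loglik(data) -> float:
    """Log likelihood of the saturated binomial model (each cell its own s).

    Cells with n == 0 contribute 0; cells with k == 0 or k == n use the
    0 log 0 = 0 convention.
    """
    n = data.n.astype(float)
    k = data.k.astype(float)
    obs = n > 0
    no, ko = n[obs], k[obs]
    p = ko / no
    logC = gammaln(no + 1) - gammaln(ko + 1) - gammaln(no - ko + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(ko > 0, ko * np.log(np.where(ko > 0, p, 1.0)), 0.0)
        term = term + np.where(
            no - ko > 0, (no - ko) * np.log(np.where(no > ko, 1 - p, 1.0)), 0.0
        )
    return float(np.sum(logC + term))
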