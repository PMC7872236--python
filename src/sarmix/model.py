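"""Model and results objects for smolt-to-adult return (SAR) estimation.

:class:`SARModel` binds a cohort lattice, a covariate matrix and a
:class:`~sarmix.params.ModelSpec`; :meth:`SARModel.fit` maximises the
Laplace marginal likelihood with a quasi-Newton optimiser over
unconstrained transforms (log for scales, atanh for correlations) and
returns a :class:`SARResults` carrying estimates, standard errors,
latent-effect modes, the marginal AIC and convergence diagnostics.
Derived quantities — daily and annual survival surfaces with confidence
intervals, covariate-effect curves — hang off the results object, and
unconditional simulation hangs off the model.

Convergence follows the usual mixed-model criterion: a positive-definite
outer Hessian and a maximum absolute gradient component of at most 0.001.
A fit that fails this is returned flagged, never raised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .cohorts import CohortTable
from .laplace import InnerOptimizationError, LaplaceProblem
from .params import (
    CORRELATION_PARAMS,
    ModelSpec,
    ParameterSet,
    RandomEffects,
    spec_param_names,
)

__all__ = ["SARModel", "SARResults", "fit", "simulate"]

GRADIENT_TOL = 1e-3  # convergence criterion on the outer gradient
Z_BOUNDS = {"mu": (-30.0, 10.0), "beta": (-20.0, 20.0),
            "corr": (-7.0, 7.0), "scale": (-12.0, 4.0)}

SCALE_PARAMS = frozenset({"psi", "phi", "sigma"})


def _kind(name: str) -> str:
    if name == "mu":
        return "mu"
    if name.startswith("beta:"):
        return "beta"
    if name in CORRELATION_PARAMS:
        return "corr"
    if name in SCALE_PARAMS:
        return "scale"
    raise KeyError(name)


def _to_z(name: str, value: float) -> float:
    k = _kind(name)
    if k == "corr":
        return float(np.arctanh(value))
    if k == "scale":
        return float(np.log(value))
    return float(value)


def _from_z(name: str, z: float) -> float:
    k = _kind(name)
    if k == "corr":
        return float(np.tanh(z))
    if k == "scale":
        return float(np.exp(z))
    return float(z)


def _dtheta_dz(name: str, theta_val: float) -> float:
    k = _kind(name)
    if k == "corr":
        return 1.0 - theta_val**2
    if k == "scale":
        return theta_val
    return 1.0


class SARModel:
    """Mixed-effects binomial SAR model on a day-by-year cohort lattice."""

    def __init__(self, data: CohortTable, covariates=None,
                 spec: ModelSpec | None = None, *, gaussian_obs=None):
        self.data = data
        self.X = covariates
        self.spec = spec if spec is not None else ModelSpec()
        self.problem = LaplaceProblem(self.spec, data, covariates,
                                      gaussian_obs=gaussian_obs)
        self.param_names = spec_param_names(self.spec)

    @classmethod
    def from_frames(cls, cohort_frame: pd.DataFrame, covariate_frame=None,
                    spec: ModelSpec | None = None,
                    rear_type: str | None = None) -> "SARModel":
        """Build from tidy frames (cohorts: rear_type/year/day/n/k;
        covariates: year-indexed wide table, already standardised)."""
        from .covariates import CovariateMatrix

        table = CohortTable.from_frame(cohort_frame, rear_type=rear_type)
        X = None
        if covariate_frame is not None:
            cf = covariate_frame
            if "year" in cf.columns:
                cf = cf.set_index("year")
            X = CovariateMatrix(cf.index.to_numpy(), list(cf.columns),
                                cf.to_numpy())
        return cls(table, X, spec)

    # ----- likelihood access ----------------------------------------------
    def loglike(self, params: ParameterSet) -> float:
        """Marginal log likelihood at ``params``."""
        value, _ = self.problem.marginal_nll(params)
        return -value

    def _theta_from_zfull(self, zfull: np.ndarray) -> ParameterSet:
        vals = {n: _from_z(n, z) for n, z in zip(self.param_names, zfull)}
        beta = np.array([vals[f"beta:{c}"] for c in self.spec.covariates])
        kw = {p: vals[p] for p in self.spec.variance_params}
        return ParameterSet(mu=vals["mu"], beta=beta, **kw)

    def _default_start(self) -> ParameterSet:
        ntot = max(self.data.n_total, 1)
        rate = np.clip(self.data.k_total / ntot, 1e-6, 1 - 1e-6)
        kw = {}
        for p in self.spec.variance_params:
            kw[p] = 0.2 if p in CORRELATION_PARAMS else 0.5
        return ParameterSet(mu=float(logit(rate)),
                            beta=np.zeros(len(self.spec.covariates)), **kw)

    # ----- fitting ----------------------------------------------------------
    def fit(self, start: ParameterSet | None = None,
            fixed: Mapping[str, float] | None = None,
            maxiter: int = 300, compute_se: bool = True,
            gtol: float = 1e-6) -> "SARResults":
        """Maximise the Laplace marginal likelihood.

        Parameters
        ----------
        start
            Starting parameters (defaults to a data-driven neutral start).
        fixed
            Parameters pinned at given natural-scale values and excluded
            from estimation (and from the AIC parameter count).
        compute_se
            Compute the outer Hessian (finite differences of the analytic
            gradient), standard errors and the positive-definiteness flag.

        Never raises on non-convergence: failures come back as a results
        object with ``converged=False``.
        """
        fixed = dict(fixed or {})
        unknown = set(fixed) - set(self.param_names)
        if unknown:
            raise KeyError(f"fixed parameter(s) not in model: {sorted(unknown)}")
        start_ps = start if start is not None else self._default_start()
        start_ps.validate_for(self.spec)
        zfull0 = np.array(
            [_to_z(n, v) for n, v in
             zip(self.param_names,
                 _flatten(start_ps, self.spec, self.param_names))])
        free = [i for i, n in enumerate(self.param_names) if n not in fixed]
        for name, val in fixed.items():
            zfull0[self.param_names.index(name)] = _to_z(name, val)
        bounds = [Z_BOUNDS[_kind(self.param_names[i])] for i in free]
        zfull0[free] = np.clip(zfull0[free],
                               [b[0] for b in bounds], [b[1] for b in bounds])

        nfev = [0]

        def val_and_grad(zfree):
            zfull = zfull0.copy()
            zfull[free] = zfree
            theta = self._theta_from_zfull(zfull)
            nfev[0] += 1
            try:
                value, grads, _ = self.problem.marginal_nll_grad(theta)
            except (InnerOptimizationError, FloatingPointError):
                return np.inf, np.zeros(len(free))
            gz = np.array([
                grads[self.param_names[i]]
                * _dtheta_dz(self.param_names[i], _from_z(
                    self.param_names[i], zfull[i]))
                for i in free])
            return value, gz

        failure: str | None = None
        try:
            opt = minimize(val_and_grad, zfull0[free], jac=True,
                           method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": maxiter, "ftol": 1e-12,
                                    "gtol": gtol})
            zhat_free = opt.x
            value, gz = val_and_grad(zhat_free)
            if not np.isfinite(value):
                raise InnerOptimizationError("objective not finite at optimum")
        except (InnerOptimizationError, FloatingPointError,
                np.linalg.LinAlgError) as exc:
            failure = str(exc)
            zhat_free = zfull0[free]
            value, gz = np.nan, np.full(len(free), np.nan)

        zfull = zfull0.copy()
        zfull[free] = zhat_free
        theta_hat = self._theta_from_zfull(zfull)
        max_grad = float(np.max(np.abs(gz))) if len(free) else 0.0
        at_bound = bool(np.any(
            (np.abs(zhat_free - np.array([b[0] for b in bounds])) < 1e-6)
            | (np.abs(zhat_free - np.array([b[1] for b in bounds])) < 1e-6)
        )) if len(free) else False

        try:
            _, re_modes = self.problem.marginal_nll(theta_hat)
        except InnerOptimizationError:
            re_modes = RandomEffects.zeros(*self.data.shape)
            failure = failure or "latent modes unavailable at optimum"

        hessian_pd = False
        cov_z = None
        se: dict[str, float] = {}
        if failure is None and compute_se and len(free):
            Hz = self._outer_hessian(val_and_grad, zhat_free)
            if np.all(np.isfinite(Hz)):
                eig = np.linalg.eigvalsh(Hz)
                hessian_pd = bool(eig.min() > 0)
                if hessian_pd:
                    cov_z = np.linalg.inv(Hz)
                    dz = np.array([
                        _dtheta_dz(self.param_names[i],
                                   _from_z(self.param_names[i], zfull[i]))
                        for i in free])
                    se_z = np.sqrt(np.maximum(np.diag(cov_z), 0.0))
                    for j, i in enumerate(free):
                        se[self.param_names[i]] = float(se_z[j] * abs(dz[j]))
        elif failure is None and not compute_se:
            hessian_pd = True  # not assessed; convergence judged on gradient

        degenerate = self.data.k_total in (0, self.data.n_total)
        if degenerate:
            failure = failure or (
                "degenerate data: every cohort outcome identical, "
                "mean survival diverges on the logit scale")
        converged = (failure is None and hessian_pd
                     and max_grad <= GRADIENT_TOL and not at_bound)
        k = len(free)
        llf = -value if np.isfinite(value) else np.nan
        return SARResults(
            model=self, spec=self.spec, params=theta_hat, se=se,
            re_modes=re_modes, llf=llf, aic=2.0 * k - 2.0 * llf,
            k_params=k, max_gradient=max_grad, hessian_pd=hessian_pd,
            converged=converged, cov_z=cov_z,
            free_names=[self.param_names[i] for i in free],
            fixed=fixed, n_inner=self.problem.D, nfev=nfev[0],
            failure=failure, at_bound=at_bound,
        )

    @staticmethod
    def _outer_hessian(val_and_grad, zhat: np.ndarray,
                       h: float = 1e-4) -> np.ndarray:
        p = zhat.size
        H = np.zeros((p, p))
        for i in range(p):
            zp = zhat.copy()
            zp[i] += h
            _, gp = val_and_grad(zp)
            zm = zhat.copy()
            zm[i] -= h
            _, gm = val_and_grad(zm)
            H[:, i] = (gp - gm) / (2.0 * h)
        return 0.5 * (H + H.T)

    # ----- simulation -------------------------------------------------------
    def simulate(self, params: ParameterSet, seed,
                 lattice=None, return_effects: bool = False):
        """Unconditional simulation on this model's lattice (or ``lattice``)."""
        n = self.data.n if lattice is None else lattice
        return simulate(params, self.spec, n, self.X, seed,
                        days=self.data.days, years=self.data.years,
                        rear_type=self.data.rear_type,
                        return_effects=return_effects)


def _flatten(ps: ParameterSet, spec: ModelSpec,
             names: Sequence[str]) -> list[float]:
    vals = {"mu": ps.mu}
    for c, b in zip(spec.covariates, ps.beta):
        vals[f"beta:{c}"] = float(b)
    for p in spec.variance_params:
        vals[p] = float(getattr(ps, p))
    return [vals[n] for n in names]


def fit(spec: ModelSpec, data: CohortTable, X=None, **opts) -> "SARResults":
    """Functional wrapper: build a :class:`SARModel` and fit it."""
    return SARModel(data, X, spec).fit(**opts)


def simulate(theta: ParameterSet, spec: ModelSpec, lattice, X, seed,
             *, days=None, years=None, rear_type: str = "wild",
             return_effects: bool = False):
    """Unconditional simulation of a cohort table.

    Draw the active latent processes from their stationary laws, form the
    survival surface through the logistic link, and draw binomial adult
    returns cell by cell.  The migrant layout ``lattice`` (an ``n_jt``
    array or a :class:`CohortTable`) is preserved exactly.
    """
    if isinstance(lattice, CohortTable):
        days = lattice.days
        years = lattice.years
        rear_type = lattice.rear_type
        n = lattice.n
    else:
        n = np.asarray(lattice)
        if days is None:
            days = np.arange(100, 100 + n.shape[0])
        if years is None:
            years = np.arange(2000, 2000 + n.shape[1])
    theta.validate_for(spec)
    J, T = n.shape
    rng = np.random.default_rng(seed)
    eff = RandomEffects.zeros(J, T)
    if "day" in spec.random:
        eff.nu = _draw_ar1(rng, J, theta.tau, theta.psi)
    if "year" in spec.random:
        eff.omega = _draw_ar1(rng, T, theta.pi, theta.phi)
    if "dayyear" in spec.random:
        eff.xi = _draw_field(rng, J, T, theta.rho, theta.gamma, theta.sigma)
    if theta.beta.size:
        x = X.align(years, spec.covariates)
    else:
        x = np.zeros((T, 0))
    from .likelihood import eta_surface

    eta = eta_surface(theta, eff, x)
    k = rng.binomial(n.astype(int), expit(eta))
    table = CohortTable(rear_type, days, years, n, k)
    if return_effects:
        return table, eff
    return table


def _draw_ar1(rng, m: int, corr: float, scale: float) -> np.ndarray:
    v = np.empty(m)
    v[0] = rng.normal(0.0, scale / np.sqrt(1.0 - corr**2))
    innov = rng.normal(0.0, scale, size=m - 1)
    for i in range(1, m):
        v[i] = corr * v[i - 1] + innov[i - 1]
    return v


def _draw_field(rng, J: int, T: int, rho: float, gamma: float,
                sigma: float) -> np.ndarray:
    """Year-to-year AR(1) of day vectors with AR(1) day covariance Sigma."""
    xi = np.empty((J, T))
    # innovation: day-AR(1) vector with marginal sd sigma / sqrt(1 - rho^2)
    def day_vec():
        return _draw_ar1(rng, J, rho, sigma)

    xi[:, 0] = day_vec() / np.sqrt(1.0 - gamma**2)
    for t in range(1, T):
        xi[:, t] = gamma * xi[:, t - 1] + day_vec()
    return xi


@dataclass
class SARResults:
    """Fit of a :class:`SARModel`: estimates, uncertainty, diagnostics."""

    model: SARModel
    spec: ModelSpec
    params: ParameterSet
    se: dict[str, float]
    re_modes: RandomEffects
    llf: float
    aic: float
    k_params: int
    max_gradient: float
    hessian_pd: bool
    converged: bool
    cov_z: np.ndarray | None
    free_names: list[str]
    fixed: dict[str, float] = field(default_factory=dict)
    n_inner: int = 0
    nfev: int = 0
    failure: str | None = None
    at_bound: bool = False

    # Report labels: the field's customary symbols for each parameter.
    REPORT_LABELS = {
        "mu": "mu (mean logit survival)",
        "tau": "tau (day-effect correlation)",
        "psi": "psi (day-effect innovation sd)",
        "pi": "pi_yr (year-effect correlation)",
        "phi": "phi_yr (year-effect innovation sd)",
        "rho": "rho (day corr. of day/year field)",
        "gamma": "pi (year corr. of day/year field)",
        "sigma": "phi (day/year-field innovation sd)",
    }

    def _require_converged(self) -> None:
        if not self.converged:
            raise RuntimeError(
                "fit did not converge "
                f"(max|grad|={self.max_gradient:.3g}, "
                f"PD Hessian={self.hessian_pd}, at_bound={self.at_bound}"
                + (f", failure: {self.failure}" if self.failure else "")
                + ")"
            )

    # ----- parameter access -------------------------------------------------
    def params_dict(self) -> dict[str, float]:
        return self.params.to_dict(self.spec)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Normal-approximation intervals, transformed to the natural scale.

        Intervals are computed on the unconstrained scale (log / atanh)
        and mapped back, so they respect the parameter domains.
        """
        from scipy.stats import norm

        zq = norm.ppf(1.0 - alpha / 2.0)
        if self.cov_z is None:
            raise RuntimeError("no covariance available (fit not converged?)")
        se_z = np.sqrt(np.maximum(np.diag(self.cov_z), 0.0))
        vals = dict(zip(self.model.param_names,
                        _flatten(self.params, self.spec,
                                 self.model.param_names)))
        rows = []
        for name, s in zip(self.free_names, se_z):
            z0 = _to_z(name, vals[name])
            rows.append({
                "param": name,
                "estimate": vals[name],
                "lo": _from_z(name, z0 - zq * s),
                "hi": _from_z(name, z0 + zq * s),
            })
        return pd.DataFrame(rows).set_index("param")

    @property
    def mean_survival(self) -> float:
        """Survival at mean covariates with latent effects at zero."""
        return float(expit(self.params.mu))

    def mean_survival_interval(self, alpha: float = 0.05) -> tuple[float, float]:
        ci = self.conf_int(alpha)
        return float(expit(ci.loc["mu", "lo"])), float(expit(ci.loc["mu", "hi"]))

    # ----- derived surfaces ---------------------------------------------
    def _latent_cov(self):
        if not hasattr(self, "_latent_cov_cache"):
            eps, Hinv = self.model.problem.conditional_latent_cov(self.params)
            self._latent_cov_cache = (eps, Hinv)
        return self._latent_cov_cache

    def _fixed_var_by_year(self) -> np.ndarray:
        """d' C d per year for d = (1, x_t) over the free (mu, beta) block."""
        T = self.model.data.years.size
        if self.cov_z is None:
            return np.zeros(T)
        fixed_names = ["mu"] + [f"beta:{c}" for c in self.spec.covariates]
        idx = [self.free_names.index(n) for n in fixed_names
               if n in self.free_names]
        names = [self.free_names[i] for i in idx]
        C = self.cov_z[np.ix_(idx, idx)]
        x = self.model.problem.x
        out = np.empty(T)
        for t in range(T):
            d = []
            for n_ in names:
                if n_ == "mu":
                    d.append(1.0)
                else:
                    c = n_.split(":", 1)[1]
                    d.append(x[t, self.spec.covariates.index(c)])
            d = np.asarray(d)
            out[t] = float(d @ C @ d)
        return out

    def predict_daily_survival(self, alpha: float = 0.05) -> pd.DataFrame:
        """Daily survival surface with pointwise confidence intervals.

        Intervals are formed on the logit scale (fixed-effect delta-method
        variance plus the conditional latent variance from the joint
        precision) and mapped through the inverse logit, so they stay
        inside (0, 1).
        """
        self._require_converged()
        from scipy.stats import norm

        prob = self.model.problem
        data = self.model.data
        zq = norm.ppf(1.0 - alpha / 2.0)
        eps, Hinv = self._latent_cov()
        from .likelihood import eta_surface

        eta = eta_surface(self.params, self.re_modes, prob.x)
        V = (prob._conditional_cell_var(Hinv) if prob.D
             else np.zeros(data.shape[0] * data.shape[1]))
        var_fix = self._fixed_var_by_year()
        var = V.reshape(data.shape, order="F") + var_fix[None, :]
        se_eta = np.sqrt(var)
        jj, tt = np.meshgrid(np.arange(data.days.size),
                             np.arange(data.years.size), indexing="ij")
        return pd.DataFrame({
            "day": data.days[jj.ravel()],
            "year": data.years[tt.ravel()],
            "n": data.n.ravel(),
            "k": data.k.ravel(),
            "eta": eta.ravel(),
            "se_eta": se_eta.ravel(),
            "survival": expit(eta).ravel(),
            "lo": expit(eta - zq * se_eta).ravel(),
            "hi": expit(eta + zq * se_eta).ravel(),
        })

    def annual_survival(self, alpha: float = 0.05) -> pd.DataFrame:
        """Arrival-weighted annual survival S_t with delta-method intervals.

        S_t = sum_j n_jt s_jt / sum_j n_jt; years with no migrants come
        back as missing.
        """
        self._require_converged()
        from scipy.stats import norm

        prob = self.model.problem
        data = self.model.data
        zq = norm.ppf(1.0 - alpha / 2.0)
        _, Hinv = self._latent_cov()
        from .likelihood import eta_surface

        eta = eta_surface(self.params, self.re_modes, prob.x)
        s = expit(eta)
        var_fix = self._fixed_var_by_year()
        J = data.days.size
        rows = []
        for t, year in enumerate(data.years):
            n_t = data.n[:, t].astype(float)
            ntot = n_t.sum()
            if ntot == 0:
                rows.append({"year": int(year), "survival": np.nan,
                             "se": np.nan, "lo": np.nan, "hi": np.nan})
                continue
            w = n_t / ntot
            S = float(w @ s[:, t])
            a = w * s[:, t] * (1.0 - s[:, t])  # dS/deta_j
            cov = np.full((J, J), var_fix[t])
            if prob.D:
                idxs = []
                if "day" in prob.offsets:
                    idxs.append(prob.offsets["day"] + np.arange(J))
                if "year" in prob.offsets:
                    idxs.append(np.full(J, prob.offsets["year"] + t))
                if "dayyear" in prob.offsets:
                    idxs.append(prob.offsets["dayyear"] + t * J
                                + np.arange(J))
                for ia in idxs:
                    for ib in idxs:
                        cov = cov + Hinv[np.ix_(ia, ib)]
            var_S = float(a @ cov @ a)
            se = np.sqrt(max(var_S, 0.0))
            rows.append({"year": int(year), "survival": S, "se": se,
                         "lo": max(S - zq * se, 0.0),
                         "hi": min(S + zq * se, 1.0)})
        return pd.DataFrame(rows)

    def covariate_effect_curve(self, covariate: str,
                               grid=None) -> pd.DataFrame:
        """Percent change in survival vs a standardised covariate.

        100 * (s(mu + beta_c x) - s(mu)) / s(mu) over ``grid`` with the
        other covariates held at zero.
        """
        if covariate not in self.spec.covariates:
            raise KeyError(f"{covariate!r} not in model covariates "
                           f"{self.spec.covariates}")
        if grid is None:
            grid = np.linspace(-2.0, 2.0, 81)
        grid = np.asarray(grid, dtype=float)
        b = self.params.beta[self.spec.covariates.index(covariate)]
        s0 = expit(self.params.mu)
        s = expit(self.params.mu + b * grid)
        return pd.DataFrame({
            "x": grid,
            "pct_change": 100.0 * (s - s0) / s0,
        })

    # ----- reporting ------------------------------------------------------
    def summary(self) -> str:
        data = self.model.data
        lines = [
            "SAR mixed-effects binomial model"
            f" ({data.rear_type}, {data.days[0]}-{data.days[-1]} x "
            f"{data.years[0]}-{data.years[-1]})",
            f"  covariates: {', '.join(self.spec.covariates) or 'none'}",
            f"  random components: {', '.join(self.spec.active) or 'none'}",
            f"  log-marginal-likelihood {self.llf:.4f}   AIC {self.aic:.4f}"
            f"   k={self.k_params}",
            f"  max|gradient| {self.max_gradient:.2e}   "
            f"PD Hessian: {self.hessian_pd}   converged: {self.converged}",
            "",
            f"  {'parameter':<38}{'estimate':>10}{'std err':>10}",
        ]
        vals = self.params_dict()
        for name in self.model.param_names:
            base = name.split(":", 1)[0]
            label = (f"beta[{name.split(':', 1)[1]}]" if base == "beta"
                     else self.REPORT_LABELS.get(name, name))
            se = self.se.get(name)
            se_s = f"{se:10.4f}" if se is not None else f"{'--':>10}"
            note = "  (fixed)" if name in self.fixed else ""
            lines.append(f"  {label:<38}{vals[name]:10.4f}{se_s}{note}")
        if self.converged:
            lo, hi = self.mean_survival_interval()
            lines.append("")
            lines.append(
                f"  mean survival {self.mean_survival:.4f} "
                f"(95% CI {lo:.4f}, {hi:.4f})")
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "spec": {"covariates": list(self.spec.covariates),
                     "random": sorted(self.spec.random)},
            "params": self.params_dict(),
            "se": self.se,
            "fixed": self.fixed,
            "llf": self.llf,
            "aic": self.aic,
            "k_params": self.k_params,
            "max_gradient": self.max_gradient,
            "hessian_pd": self.hessian_pd,
            "converged": self.converged,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    # ----- plotting -------------------------------------------------------
    def plot_daily_survival(self, years=None, ax=None):
        """Daily survival curves with CI ribbons, one panel per year."""
        import matplotlib.pyplot as plt

        surf = self.predict_daily_survival()
        years = list(years) if years is not None else list(
            self.model.data.years)
        if ax is None:
            _, ax = plt.subplots()
        for year in years:
            d = surf[surf["year"] == year]
            (line,) = ax.plot(d["day"], d["survival"], label=str(year))
            ax.fill_between(d["day"], d["lo"], d["hi"], alpha=0.2,
                            color=line.get_color())
        ax.set_xlabel("day of year")
        ax.set_ylabel("smolt-to-adult survival")
        ax.legend(fontsize="small")
        return ax

    def plot_annual_survival(self, ax=None):
        import matplotlib.pyplot as plt

        ann = self.annual_survival()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(ann["year"], ann["survival"], marker="o")
        ax.fill_between(ann["year"], ann["lo"], ann["hi"], alpha=0.2)
        ax.set_xlabel("outmigration year")
        ax.set_ylabel("annual SAR")
        return ax

    def plot_effect_curves(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for cov in self.spec.covariates:
            curve = self.covariate_effect_curve(cov)
            ax.plot(curve["x"], curve["pct_change"], label=cov)
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_xlabel("standardised covariate")
        ax.set_ylabel("% change in survival")
        ax.legend(fontsize="small")
        return ax
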