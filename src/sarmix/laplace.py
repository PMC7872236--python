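"""Laplace-approximated marginal likelihood of the SAR mixed model.

The marginal likelihood integrates the joint likelihood over the latent
effects eps = (nu, omega, xi),

    -log L(theta) ~= f(theta, eps_hat) + 1/2 log det H(eps_hat)
                     - (D/2) log 2 pi,

where f is the joint negative log likelihood, eps_hat its minimiser over
the latent effects (found by damped Newton iterations) and H the inner
Hessian d^2 f / d eps^2 = Q + A' W A, with Q the block prior precision,
A the 0/1 map from latent effects to cell predictors and W the diagonal
observation curvature.

Outer gradients are computed analytically rather than by finite
differences: the envelope theorem handles f at the mode, the prior
log-determinants have closed forms, and the log det H term differentiates
through the implicit mode via

    d eps_hat / d theta_i = -H^{-1} b_i,    b_i = d^2 f / d eps d theta_i,
    d log det H / d theta_i = tr(H^{-1} [dQ_i + A' diag(W' . d eta_i) A]),

with tr(H^{-1} A' diag(u) A) = sum_c u_c V_c and V_c the conditional
variance of the latent contribution to cell c.  All linear algebra is
dense Cholesky; the lattices this package targets stay below a few
thousand latent effects.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.special import expit

from .likelihood import (
    LOG2PI,
    ar1_scaled_precision,
    ar1_scaled_precision_dcorr,
)
from .params import ModelSpec, ParameterSet, RandomEffects

__all__ = ["LaplaceProblem", "laplace_marginal_nll", "InnerOptimizationError"]

INNER_TOL = 1e-8
INNER_MAXITER = 200


class InnerOptimizationError(RuntimeError):
    """The inner Newton solve for the latent modes failed."""


class LaplaceProblem:
    """Marginal-likelihood machinery for one model spec on one lattice.

    Parameters
    ----------
    spec
        Covariates and active latent components.
    data
        :class:`~sarmix.cohorts.CohortTable`.
    X
        :class:`~sarmix.covariates.CovariateMatrix`; may be ``None`` when
        the spec has no covariates.
    gaussian_obs
        Test hook: ``(y, sd)`` replaces the binomial observation model
        with y_jt ~ Normal(eta_jt, sd) on cells where ``data.n > 0``.
        Under a Gaussian observation model the Laplace approximation is
        exact, which pins down the approximation machinery against closed
        forms.
    """

    def __init__(self, spec: ModelSpec, data, X=None, gaussian_obs=None):
        self.spec = spec
        self.data = data
        self.J, self.T = data.shape
        if spec.covariates:
            if X is None:
                raise ValueError("spec has covariates but X is None")
            self.x = X.align(data.years, spec.covariates)
        else:
            self.x = np.zeros((self.T, 0))
        self.n = data.n.astype(float)
        self.k = data.k.astype(float)
        self.obs = self.n > 0
        self.gaussian_obs = None
        if gaussian_obs is not None:
            y, sd = gaussian_obs
            self.gaussian_obs = (np.asarray(y, dtype=float), float(sd))

        # latent layout: [nu (J) | omega (T) | xi (J*T)], active blocks only
        self.active = spec.active
        offset = 0
        self.offsets: dict[str, int] = {}
        for comp, size in (("day", self.J), ("year", self.T),
                           ("dayyear", self.J * self.T)):
            if comp in spec.random:
                self.offsets[comp] = offset
                offset += size
        self.D = offset
        # cell ordering: column-major over (J, T), c = j + t * J
        self.jgrid = np.tile(np.arange(self.J), self.T)
        self.tgrid = np.repeat(np.arange(self.T), self.J)
        self._eps_cache = np.zeros(self.D)
        self._logC = (self._log_binom_const()
                      if self.gaussian_obs is None else 0.0)

    # ----- observation model ------------------------------------------------
    def _data_terms(self, eta: np.ndarray):
        """Return (fdata, g, W, Wp): value, d/deta, d2/deta2, d3/deta3."""
        if self.gaussian_obs is not None:
            y, sd = self.gaussian_obs
            m = self.obs.astype(float)
            resid = (eta - y) * m
            fdata = float(
                np.sum(m * (0.5 * (resid / sd) ** 2
                            + np.log(sd) + 0.5 * LOG2PI))
            )
            g = m * resid / sd**2
            W = m / sd**2
            Wp = np.zeros_like(W)
            return fdata, g, W, Wp
        s = expit(eta)
        fdata = float(
            np.sum(self.n * np.logaddexp(0.0, eta) - self.k * eta)
        )
        g = self.n * s - self.k
        W = self.n * s * (1.0 - s)
        Wp = W * (1.0 - 2.0 * s)
        return fdata, g, W, Wp

    def _log_binom_const(self) -> float:
        from scipy.special import gammaln

        no, ko = self.n[self.obs], self.k[self.obs]
        return float(np.sum(gammaln(no + 1) - gammaln(ko + 1)
                            - gammaln(no - ko + 1)))

    # ----- prior ------------------------------------------------------------
    def _prior_blocks(self, theta: ParameterSet):
        """Dense prior precision blocks keyed by component."""
        blocks = {}
        if "day" in self.spec.random:
            blocks["day"] = ar1_scaled_precision(theta.tau, self.J) / theta.psi**2
        if "year" in self.spec.random:
            blocks["year"] = ar1_scaled_precision(theta.pi, self.T) / theta.phi**2
        if "dayyear" in self.spec.random:
            Mg = ar1_scaled_precision(theta.gamma, self.T)
            Mr = ar1_scaled_precision(theta.rho, self.J)
            blocks["dayyear"] = np.kron(Mg, Mr) / theta.sigma**2
        return blocks

    def _logdet_prior(self, theta: ParameterSet) -> float:
        ld = 0.0
        if "day" in self.spec.random:
            ld += np.log1p(-theta.tau**2) - 2.0 * self.J * np.log(theta.psi)
        if "year" in self.spec.random:
            ld += np.log1p(-theta.pi**2) - 2.0 * self.T * np.log(theta.phi)
        if "dayyear" in self.spec.random:
            ld += (self.T * np.log1p(-theta.rho**2)
                   + self.J * np.log1p(-theta.gamma**2)
                   - 2.0 * self.J * self.T * np.log(theta.sigma))
        return float(ld)

    def _Q_dense(self, blocks) -> np.ndarray:
        Q = np.zeros((self.D, self.D))
        for comp, block in blocks.items():
            o = self.offsets[comp]
            m = block.shape[0]
            Q[o:o + m, o:o + m] = block
        return Q

    # ----- latent-effect plumbing -------------------------------------------
    def split_eps(self, eps: np.ndarray) -> RandomEffects:
        nu = np.zeros(self.J)
        omega = np.zeros(self.T)
        xi = np.zeros((self.J, self.T))
        if "day" in self.offsets:
            o = self.offsets["day"]
            nu = eps[o:o + self.J].copy()
        if "year" in self.offsets:
            o = self.offsets["year"]
            omega = eps[o:o + self.T].copy()
        if "dayyear" in self.offsets:
            o = self.offsets["dayyear"]
            xi = eps[o:o + self.J * self.T].reshape(
                (self.J, self.T), order="F").copy()
        return RandomEffects(nu=nu, omega=omega, xi=xi)

    def _eta(self, theta: ParameterSet, eps: np.ndarray) -> np.ndarray:
        eta = np.full((self.J, self.T), theta.mu)
        if theta.beta.size:
            eta += (self.x @ theta.beta)[None, :]
        if "day" in self.offsets:
            o = self.offsets["day"]
            eta += eps[o:o + self.J][:, None]
        if "year" in self.offsets:
            o = self.offsets["year"]
            eta += eps[o:o + self.T][None, :]
        if "dayyear" in self.offsets:
            o = self.offsets["dayyear"]
            eta += eps[o:o + self.J * self.T].reshape(
                (self.J, self.T), order="F")
        return eta

    def _gather(self, field: np.ndarray) -> np.ndarray:
        """A' applied to a (J, T) cell field -> latent-space vector."""
        out = np.zeros(self.D)
        if "day" in self.offsets:
            o = self.offsets["day"]
            out[o:o + self.J] = field.sum(axis=1)
        if "year" in self.offsets:
            o = self.offsets["year"]
            out[o:o + self.T] = field.sum(axis=0)
        if "dayyear" in self.offsets:
            o = self.offsets["dayyear"]
            out[o:o + self.J * self.T] = field.ravel(order="F")
        return out

    def _scatter(self, u: np.ndarray) -> np.ndarray:
        """A applied to a latent-space vector -> flat cell vector (F order)."""
        out = np.zeros(self.J * self.T)
        if "day" in self.offsets:
            o = self.offsets["day"]
            out += u[o:o + self.J][self.jgrid]
        if "year" in self.offsets:
            o = self.offsets["year"]
            out += u[o:o + self.T][self.tgrid]
        if "dayyear" in self.offsets:
            o = self.offsets["dayyear"]
            out += u[o:o + self.J * self.T]
        return out

    def _hessian(self, Q: np.ndarray, W: np.ndarray) -> np.ndarray:
        """H = Q + A' diag(W) A assembled blockwise."""
        H = Q.copy()
        Wf = W.ravel(order="F")
        JT = self.J * self.T
        if "day" in self.offsets:
            o = self.offsets["day"]
            idx = np.arange(o, o + self.J)
            H[idx, idx] += W.sum(axis=1)
        if "year" in self.offsets:
            o = self.offsets["year"]
            idx = np.arange(o, o + self.T)
            H[idx, idx] += W.sum(axis=0)
        if "dayyear" in self.offsets:
            o = self.offsets["dayyear"]
            idx = np.arange(o, o + JT)
            H[idx, idx] += Wf
        if "day" in self.offsets and "year" in self.offsets:
            od, oy = self.offsets["day"], self.offsets["year"]
            H[od:od + self.J, oy:oy + self.T] += W
            H[oy:oy + self.T, od:od + self.J] += W.T
        if "day" in self.offsets and "dayyear" in self.offsets:
            od, of = self.offsets["day"], self.offsets["dayyear"]
            rows = od + self.jgrid
            cols = of + np.arange(JT)
            H[rows, cols] += Wf
            H[cols, rows] += Wf
        if "year" in self.offsets and "dayyear" in self.offsets:
            oy, of = self.offsets["year"], self.offsets["dayyear"]
            rows = oy + self.tgrid
            cols = of + np.arange(JT)
            H[rows, cols] += Wf
            H[cols, rows] += Wf
        return H

    # ----- inner optimisation -----------------------------------------------
    def _inner_mode(self, theta: ParameterSet, Q: np.ndarray,
                    eps0: np.ndarray | None = None):
        """Damped Newton minimisation of the joint nll over latent effects.

        Returns (eps_hat, fdata, g, W, Wp, H, chol, logdetH).
        """
        eps = (self._eps_cache.copy() if eps0 is None else
               np.asarray(eps0, dtype=float).copy())
        if eps.shape != (self.D,):
            raise ValueError(f"eps0 must have shape ({self.D},)")

        def inner_obj(e):
            fd, *_ = self._data_terms(self._eta(theta, e))
            return fd + 0.5 * float(e @ Q @ e)

        fcur = inner_obj(eps)
        if not np.isfinite(fcur):
            eps = np.zeros(self.D)
            fcur = inner_obj(eps)
        for it in range(INNER_MAXITER):
            eta = self._eta(theta, eps)
            fdata, g, W, Wp = self._data_terms(eta)
            grad = self._gather(g) + Q @ eps
            gmax = np.max(np.abs(grad)) if self.D else 0.0
            H = self._hessian(Q, W)
            chol = _chol_with_jitter(H)
            if gmax <= INNER_TOL:
                logdetH = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
                self._eps_cache = eps.copy()
                return eps, fdata, g, W, Wp, H, chol, logdetH
            step = -cho_solve(chol, grad)
            # backtracking line search on the joint inner objective
            t = 1.0
            for _ in range(40):
                trial = eps + t * step
                ftrial = inner_obj(trial)
                if np.isfinite(ftrial) and ftrial <= fcur + 1e-12 * abs(fcur):
                    break
                t *= 0.5
            else:
                raise InnerOptimizationError(
                    f"line search failed at iteration {it} "
                    f"(|grad|={gmax:.3g})"
                )
            eps = trial
            fcur = ftrial
        raise InnerOptimizationError(
            f"inner Newton did not reach |grad| <= {INNER_TOL} in "
            f"{INNER_MAXITER} iterations (last |grad|={gmax:.3g})"
        )

    # ----- marginal likelihood ----------------------------------------------
    def marginal_nll(self, theta: ParameterSet,
                     eps0: np.ndarray | None = None):
        """Negative Laplace marginal log likelihood and latent modes."""
        theta.validate_for(self.spec)
        if self.D == 0:
            eta = self._eta(theta, np.zeros(0))
            fdata, *_ = self._data_terms(eta)
            value = fdata
            if self.gaussian_obs is None:
                value -= self._logC
            return value, self.split_eps(np.zeros(0))
        blocks = self._prior_blocks(theta)
        Q = self._Q_dense(blocks)
        eps, fdata, g, W, Wp, H, chol, logdetH = self._inner_mode(
            theta, Q, eps0)
        value = (fdata + 0.5 * float(eps @ Q @ eps)
                 - 0.5 * self._logdet_prior(theta) + 0.5 * logdetH)
        if self.gaussian_obs is None:
            value -= self._logC
        return value, self.split_eps(eps)

    def marginal_nll_grad(self, theta: ParameterSet,
                          eps0: np.ndarray | None = None):
        """Value, analytic gradient (dict by parameter name) and modes."""
        theta.validate_for(self.spec)
        names = _theta_names(self.spec)
        if self.D == 0:
            eta = self._eta(theta, np.zeros(0))
            fdata, g, W, Wp = self._data_terms(eta)
            value = fdata
            if self.gaussian_obs is None:
                value -= self._logC
            grads = {"mu": float(g.sum())}
            for m, name in enumerate(self.spec.covariates):
                grads[f"beta:{name}"] = float(g.sum(axis=0) @ self.x[:, m])
            return value, grads, self.split_eps(np.zeros(0))

        blocks = self._prior_blocks(theta)
        Q = self._Q_dense(blocks)
        eps, fdata, g, W, Wp, H, chol, logdetH = self._inner_mode(
            theta, Q, eps0)
        value = (fdata + 0.5 * float(eps @ Q @ eps)
                 - 0.5 * self._logdet_prior(theta) + 0.5 * logdetH)
        if self.gaussian_obs is None:
            value -= self._logC

        Hinv = cho_solve(chol, np.eye(self.D))
        V = self._conditional_cell_var(Hinv)
        Wpf = Wp.ravel(order="F")
        JT = self.J * self.T

        # dQ blocks and prior log-det derivatives per variance parameter
        dQ_info = self._dQ_blocks(theta, blocks)

        # second cross-derivatives b_i = d^2 f / d eps d theta_i
        b_cols: list[np.ndarray] = []
        direct: list[float] = []
        deta_direct: list[np.ndarray] = []
        trace_prior: list[float] = []
        for name in names:
            if name == "mu":
                b_cols.append(self._gather(W))
                direct.append(float(g.sum()))
                deta_direct.append(np.ones(JT))
                trace_prior.append(0.0)
            elif name.startswith("beta:"):
                m = self.spec.covariates.index(name.split(":", 1)[1])
                xm = self.x[:, m]
                b_cols.append(self._gather(W * xm[None, :]))
                direct.append(float(g.sum(axis=0) @ xm))
                deta_direct.append(np.repeat(xm, self.J))
                trace_prior.append(0.0)
            else:
                comp, dQ, dlogdet = dQ_info[name]
                o = self.offsets[comp]
                m = dQ.shape[0]
                eblock = eps[o:o + m]
                b = np.zeros(self.D)
                b[o:o + m] = dQ @ eblock
                b_cols.append(b)
                direct.append(0.5 * float(eblock @ dQ @ eblock)
                              - 0.5 * dlogdet)
                deta_direct.append(np.zeros(JT))
                trace_prior.append(float(
                    np.sum(Hinv[o:o + m, o:o + m] * dQ)))

        B = np.column_stack(b_cols) if b_cols else np.zeros((self.D, 0))
        U = cho_solve(chol, B)
        grads: dict[str, float] = {}
        for i, name in enumerate(names):
            deta = deta_direct[i] - self._scatter(U[:, i])
            grads[name] = (direct[i] + 0.5 * trace_prior[i]
                           + 0.5 * float((Wpf * V) @ deta))
        return value, grads, self.split_eps(eps)

    def _conditional_cell_var(self, Hinv: np.ndarray) -> np.ndarray:
        """V_c = (A H^{-1} A')_cc, flat in cell (F) order."""
        JT = self.J * self.T
        V = np.zeros(JT)
        idx = {}
        if "day" in self.offsets:
            idx["day"] = self.offsets["day"] + self.jgrid
        if "year" in self.offsets:
            idx["year"] = self.offsets["year"] + self.tgrid
        if "dayyear" in self.offsets:
            idx["dayyear"] = self.offsets["dayyear"] + np.arange(JT)
        comps = list(idx)
        for a in comps:
            V += Hinv[idx[a], idx[a]]
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                V += 2.0 * Hinv[idx[comps[i]], idx[comps[j]]]
        return V

    def _dQ_blocks(self, theta: ParameterSet, blocks):
        """Per variance parameter: (component, dQ_block, d logdetQ)."""
        out = {}
        if "day" in self.spec.random:
            Mt = ar1_scaled_precision(theta.tau, self.J)
            dMt = ar1_scaled_precision_dcorr(theta.tau, self.J)
            out["tau"] = ("day", dMt / theta.psi**2,
                          -2.0 * theta.tau / (1.0 - theta.tau**2))
            out["psi"] = ("day", -2.0 * blocks["day"] / theta.psi,
                          -2.0 * self.J / theta.psi)
        if "year" in self.spec.random:
            dMp = ar1_scaled_precision_dcorr(theta.pi, self.T)
            out["pi"] = ("year", dMp / theta.phi**2,
                         -2.0 * theta.pi / (1.0 - theta.pi**2))
            out["phi"] = ("year", -2.0 * blocks["year"] / theta.phi,
                          -2.0 * self.T / theta.phi)
        if "dayyear" in self.spec.random:
            Mg = ar1_scaled_precision(theta.gamma, self.T)
            Mr = ar1_scaled_precision(theta.rho, self.J)
            dMg = ar1_scaled_precision_dcorr(theta.gamma, self.T)
            dMr = ar1_scaled_precision_dcorr(theta.rho, self.J)
            s2 = theta.sigma**2
            out["rho"] = ("dayyear", np.kron(Mg, dMr) / s2,
                          -2.0 * self.T * theta.rho / (1.0 - theta.rho**2))
            out["gamma"] = ("dayyear", np.kron(dMg, Mr) / s2,
                            -2.0 * self.J * theta.gamma
                            / (1.0 - theta.gamma**2))
            out["sigma"] = ("dayyear", -2.0 * blocks["dayyear"] / theta.sigma,
                            -2.0 * self.J * self.T / theta.sigma)
        return out

    def conditional_latent_cov(self, theta: ParameterSet,
                               eps0: np.ndarray | None = None):
        """(eps_hat, H^{-1}) at the latent mode for a given theta.

        H^{-1} is the Gaussian (Laplace) approximation to the conditional
        covariance of the latent effects given the data; used for
        prediction intervals.
        """
        blocks = self._prior_blocks(theta)
        Q = self._Q_dense(blocks)
        eps, _, _, _, _, H, chol, _ = self._inner_mode(theta, Q, eps0)
        return eps, cho_solve(chol, np.eye(self.D))


def _chol_with_jitter(H: np.ndarray):
    """Cholesky with a small escalating jitter; H is PD in exact arithmetic
    (prior precision PD, observation curvature PSD)."""
    jitter = 0.0
    for _ in range(6):
        try:
            return cho_factor(
                H + jitter * np.eye(H.shape[0]) if jitter else H,
                lower=True)
        except LinAlgError:
            jitter = 1e-10 if jitter == 0.0 else jitter * 100.0
    raise InnerOptimizationError(
        "inner Hessian not positive definite even with jitter")


def _theta_names(spec: ModelSpec) -> list[str]:
    names = ["mu"] + [f"beta:{c}" for c in spec.covariates]
    names += list(spec.variance_params)
    return names


def laplace_marginal_nll(theta: ParameterSet, data, X=None,
                         spec: ModelSpec | None = None,
                         gaussian_obs=None):
    """Convenience wrapper: Laplace marginal nll and inner modes.

    The spec is inferred from which variance parameters are set on
    ``theta`` when not given; covariates are then the first columns of X.
    """
    if spec is None:
        random = set()
        if theta.tau is not None:
            random.add("day")
        if theta.pi is not None:
            random.add("year")
        if theta.rho is not None:
            random.add("dayyear")
        covs = tuple(X.names[: theta.beta.size]) if theta.beta.size else ()
        spec = ModelSpec(covariates=covs, random=frozenset(random))
    prob = LaplaceProblem(spec, data, X, gaussian_obs=gaussian_obs)
    return prob.marginal_nll(theta)
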