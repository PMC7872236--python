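"""Parameter containers for the SAR mixed-effects model.

The model's logit-scale linear predictor for the cohort passing on day *j*
of year *t* is

    eta_jt = mu + beta . x_t + nu_j + omega_t + xi_jt

with three optional latent components: a stationary AR(1) day effect
``nu`` (correlation ``tau``, innovation scale ``psi``), a stationary AR(1)
year effect ``omega`` (``pi``, ``phi``), and a separable AR(1)-by-AR(1)
day-by-year field ``xi`` (within-year day correlation ``rho``, across-year
correlation ``gamma``, innovation scale ``sigma``).

Correlations live strictly inside (-1, 1) and scales are strictly positive.
Each AR(1) component is parameterised so that its *marginal* (stationary)
variance is ``scale**2 / (1 - corr**2)``; equivalently the one-step
innovation standard deviation is ``scale``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


import numpy as np

__all__ = ["ModelSpec", "ParameterSet", "RandomEffects", "RANDOM_COMPONENTS"]

#: Recognised latent components, in canonical order.
RANDOM_COMPONENTS = ("day", "year", "dayyear")

#: Variance/correlation parameters owned by each latent component.
COMPONENT_PARAMS = {
    "day": ("tau", "psi"),
    "year": ("pi", "phi"),
    "dayyear": ("rho", "gamma", "sigma"),
}

#: Which of a component's parameters are correlations (the rest are scales).
CORRELATION_PARAMS = frozenset({"tau", "pi", "rho", "gamma"})


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: covariate names plus active latent components.

    The candidate space is deliberately constrained: at most two covariates
    and at most two of the three latent components may be active at once
    (three random processes over-fit the lattice).
    """

    covariates: tuple[str, ...] = ()
    random: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "random", frozenset(self.random))
        if len(self.covariates) > 2:
            raise ValueError("at most two covariates per model")
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("duplicate covariate in spec")
        unknown = self.random - set(RANDOM_COMPONENTS)
        if unknown:
            raise ValueError(f"unknown random components: {sorted(unknown)}")
        if len(self.random) > 2:
            raise ValueError("at most two random components per model")

    @property
    def active(self) -> tuple[str, ...]:
        """Active components in canonical order."""
        return tuple(c for c in RANDOM_COMPONENTS if c in self.random)

    @property
    def variance_params(self) -> tuple[str, ...]:
        return tuple(p for c in self.active for p in COMPONENT_PARAMS[c])

    @property
    def n_params(self) -> int:
        """Number of estimated parameters (mu + betas + variance params).

        This is the *k* of the marginal AIC; latent-effect modes are not
        counted.
        """
        return 1 + len(self.covariates) + len(self.variance_params)

    def label(self) -> str:
        cov = "+".join(self.covariates) if self.covariates else "none"
        ran = "+".join(self.active) if self.random else "none"
        return f"cov[{cov}] re[{ran}]"


@dataclass
class ParameterSet:
    """Fixed effects and variance/correlation parameters.

    Inactive components carry ``None`` for their parameters.
    """

    mu: float
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    tau: float | None = None
    psi: float | None = None
    pi: float | None = None
    phi: float | None = None
    rho: float | None = None
    gamma: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        for name in CORRELATION_PARAMS:
            v = getattr(self, name)
            if v is not None and not (-1.0 < v < 1.0):
                raise ValueError(f"{name}={v} must lie strictly in (-1, 1)")
        for name in ("psi", "phi", "sigma"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name}={v} must be strictly positive")

    def validate_for(self, spec: ModelSpec) -> None:
        if self.beta.shape != (len(spec.covariates),):
            raise ValueError(
                f"beta has length {self.beta.size}, spec has "
                f"{len(spec.covariates)} covariates"
            )
        for comp in RANDOM_COMPONENTS:
            for p in COMPONENT_PARAMS[comp]:
                v = getattr(self, p)
                if comp in spec.random and v is None:
                    raise ValueError(f"{p} required for active component {comp}")

    def replace(self, **kw) -> "ParameterSet":
        return replace(self, **kw)

    def to_dict(self, spec: ModelSpec | None = None) -> dict[str, float]:
        out = {"mu": float(self.mu)}
        names = spec.covariates if spec is not None else [
            f"beta{i + 1}" for i in range(self.beta.size)
        ]
        for name, b in zip(names, self.beta):
            out[f"beta:{name}"] = float(b)
        for p in ("tau", "psi", "pi", "phi", "rho", "gamma", "sigma"):
            v = getattr(self, p)
            if v is not None:
                out[p] = float(v)
        return out


@dataclass
class RandomEffects:
    """Realised latent effects on the day-by-year lattice.

    ``nu`` has one entry per lattice day, ``omega`` one per year and ``xi``
    is day-by-year.  Inactive components are identically zero.
    """

    nu: np.ndarray
    omega: np.ndarray
    xi: np.ndarray

    @classmethod
    def zeros(cls, n_days: int, n_years: int) -> "RandomEffects":
        return cls(
            nu=np.zeros(n_days),
            omega=np.zeros(n_years),
            xi=np.zeros((n_days, n_years)),
        )

    def __post_init__(self) -> None:
        self.nu = np.asarray(self.nu, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.xi = np.asarray(self.xi, dtype=float)
        if self.xi.shape != (self.nu.size, self.omega.size):
            raise ValueError(
                f"xi shape {self.xi.shape} does not match "
                f"(n_days={self.nu.size}, n_years={self.omega.size})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.xi.shape


def spec_param_names(spec: ModelSpec) -> list[str]:
    """Ordered names of the estimated parameters of ``spec``."""
    names = ["mu"] + [f"beta:{c}" for c in spec.covariates]
    names += list(spec.variance_params)
    return names
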