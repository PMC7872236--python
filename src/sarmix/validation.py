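"""Simulation-based validation of the SAR model.

Four instruments:

* factorial parameter-recovery experiments (simulate from known truth,
  refit, summarise percent differences) across sample size and latent
  correlation levels;
* a fixed-effects GLM comparator (day, day squared and day-by-year
  interaction terms) for bias and standard-error comparisons against the
  mixed model;
* ROC AUC as a discrimination summary for per-fish survival predictions;
* deviance ratios 1 - D_m / D_0 for nested model comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .cohorts import CohortTable
from .likelihood import eta_surface, saturated_loglik
from .model import SARModel, SARResults, simulate
from .params import ModelSpec, ParameterSet
from .synthetic import ScenarioConfig, desk_scenario, generate_arrivals, generate_covariates

__all__ = [
    "ExperimentDesign",
    "RecoverySummary",
    "run_recovery_experiment",
    "default_designs",
    "fit_glm_comparator",
    "GLMComparatorFit",
    "run_se_comparison",
    "compare_se",
    "auc",
    "cell_auc",
    "deviance_ratio",
]

EXPERIMENTS = ("sample_size", "day_corr", "field_corr")
DEFAULT_LEVELS = {
    "sample_size": (0.5, 1.0, 5.0),
    "day_corr": (0.1, 0.5, 0.9),
    "field_corr": (0.1, 0.5, 0.9),
}


@dataclass
class ExperimentDesign:
    """One factorial recovery experiment: three trials, many replicates.

    ``experiment`` selects what varies across trials: total sample size
    (as a multiple of the scenario's lattice), the day-effect correlation
    tau, or the day/year-field correlations (rho and gamma moved
    together).  The remaining truth comes from the scenario's parameter
    set.
    """

    experiment: str
    seed: int
    levels: tuple[float, ...] | None = None
    replicates: int = 100
    scenario: ScenarioConfig | None = None
    start_at_truth: bool = True

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"experiment must be one of {EXPERIMENTS}, "
                f"got {self.experiment!r}")
        if self.levels is None:
            self.levels = DEFAULT_LEVELS[self.experiment]
        self.levels = tuple(float(v) for v in self.levels)
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.scenario is None:
            self.scenario = desk_scenario(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentDesign":
        """Load a design from YAML (keys mirror the dataclass fields;
        optional ``scenario`` mapping overrides the desk scenario)."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scenario = None
        if "scenario" in raw:
            over = raw.pop("scenario")
            scenario = desk_scenario(seed=over.pop("seed", raw.get("seed", 0)),
                                     **over)
        if "levels" in raw and raw["levels"] is not None:
            raw["levels"] = tuple(raw["levels"])
        return cls(scenario=scenario, **raw)

    def truth_for(self, level: float) -> ParameterSet:
        base = self.scenario.params
        if self.experiment == "sample_size":
            return base.replace()
        if self.experiment == "day_corr":
            return base.replace(tau=level)
        return base.replace(rho=level, gamma=level)


def default_designs(seed: int, replicates: int = 100,
                    scenario: ScenarioConfig | None = None
                    ) -> list[ExperimentDesign]:
    """The three-by-three factorial: one design per experiment."""
    return [
        ExperimentDesign(experiment=exp, seed=seed + i,
                         replicates=replicates,
                         scenario=scenario.replace() if scenario else None)
        for i, exp in enumerate(EXPERIMENTS)
    ]


@dataclass
class RecoverySummary:
    """Tidy per-replicate estimates with truth, for one experiment.

    ``frame`` columns: experiment, trial, replicate, parameter, truth,
    estimate, converged, measure ('percent', or 'absolute' for truths at
    zero, where a percent difference would blow up).
    """

    experiment: str
    frame: pd.DataFrame

    def converged_frame(self) -> pd.DataFrame:
        return self.frame[self.frame["converged"]]

    def pct_diff(self) -> pd.DataFrame:
        """Percent (or flagged absolute) differences, converged only."""
        df = self.converged_frame().copy()
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * (df["estimate"] - df["truth"]) / df["truth"].abs()
        df["diff"] = np.where(df["measure"] == "percent",
                              pct, df["estimate"] - df["truth"])
        return df

    def median_bias(self) -> pd.DataFrame:
        """Median percent difference per parameter and trial."""
        df = self.pct_diff()
        return (df.groupby(["trial", "parameter"])["diff"]
                .median().unstack("parameter"))

    def iqr_table(self) -> pd.DataFrame:
        """Estimate IQR per parameter and trial (precision summary)."""
        df = self.converged_frame()

        def iqr(x):
            q1, q3 = np.percentile(x, [25, 75])
            return q3 - q1

        return (df.groupby(["trial", "parameter"])["estimate"]
                .apply(iqr).unstack("parameter"))

    def convergence_rate(self) -> pd.Series:
        return (self.frame.groupby("trial")["converged"].mean()
                .groupby(level=0).first())


def run_recovery_experiment(design: ExperimentDesign) -> RecoverySummary:
    """Simulate-and-refit replicates for every trial of one experiment.

    The covariate matrix and arrival layout are generated once per design
    (they play the role of observed inputs); each replicate draws fresh
    latent effects and binomial outcomes.  Replicate-level fit failures
    are recorded as non-converged rows, never fatal.  Deterministic given
    the design seed.
    """
    cfg = design.scenario
    gen_rng = np.random.default_rng(cfg.seed)
    n0 = generate_arrivals(cfg, gen_rng)
    X, _ = generate_covariates(cfg, gen_rng)
    spec = cfg.spec
    param_names = _recovered_names(spec)
    ss = np.random.SeedSequence(design.seed)
    child_seeds = ss.spawn(len(design.levels) * design.replicates)
    rows = []
    for li, level in enumerate(design.levels):
        truth = design.truth_for(level)
        if design.experiment == "sample_size":
            n = np.round(n0 * level).astype(int)
        else:
            n = n0
        truth_vals = truth.to_dict(spec)
        for rep in range(design.replicates):
            child = child_seeds[li * design.replicates + rep]
            sim_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            table = simulate(truth, spec, n, X, sim_seed,
                             days=cfg.days, years=np.asarray(cfg.years),
                             rear_type=cfg.rear_type)
            try:
                res = SARModel(table, X, spec).fit(
                    start=truth if design.start_at_truth else None)
                est = res.params.to_dict(spec)
                ok = bool(res.converged)
            except Exception:  # a replicate must never kill the experiment
                est = {p: np.nan for p in param_names}
                ok = False
            for p in param_names:
                tv = truth_vals[p]
                rows.append({
                    "experiment": design.experiment,
                    "trial": level,
                    "replicate": rep,
                    "parameter": p,
                    "truth": tv,
                    "estimate": est.get(p, np.nan),
                    "converged": ok,
                    "measure": "percent" if abs(tv) > 1e-8 else "absolute",
                })
    return RecoverySummary(design.experiment, pd.DataFrame(rows))


def _recovered_names(spec: ModelSpec) -> list[str]:
    return (["mu"] + [f"beta:{c}" for c in spec.covariates]
            + list(spec.variance_params))


# ---------------------------------------------------------------------------
# fixed-effects GLM comparator
# ---------------------------------------------------------------------------

@dataclass
class GLMComparatorFit:
    """Binomial GLM with day, day^2 and day-by-year interaction terms."""

    params: dict[str, float]
    bse: dict[str, float]
    converged: bool
    rank_deficient: bool
    llf: float
    n_params: int
    result: object = field(repr=False, default=None)

    @property
    def mu(self) -> float:
        return self.params["mu"]

    def beta(self, name: str) -> float:
        return self.params[f"beta:{name}"]


def _glm_design(table: CohortTable, X, covariates: Sequence[str]):
    """Design matrix on observed cells: intercept, covariates, centred
    day, day^2, and day x year-factor product terms (baseline year
    dropped)."""
    obs = table.n > 0
    jj, tt = np.nonzero(obs)
    day_c = (table.days[jj] - table.days.mean()) / 10.0  # decades of days
    cols = [np.ones(jj.size)]
    names = ["mu"]
    if covariates:
        x = X.align(table.years, covariates)
        for m, c in enumerate(covariates):
            cols.append(x[tt, m])
            names.append(f"beta:{c}")
    cols += [day_c, day_c**2]
    names += ["day", "day2"]
    for t in range(1, table.years.size):
        cols.append(day_c * (tt == t))
        names.append(f"day:year{table.years[t]}")
    M = np.column_stack(cols)
    endog = np.column_stack([table.k[jj, tt], (table.n - table.k)[jj, tt]])
    return M, endog, names


def fit_glm_comparator(table: CohortTable, X=None,
                       covariates: Sequence[str] = ()) -> GLMComparatorFit:
    """Maximum-likelihood binomial logistic regression comparator.

    All temporal structure is fixed effects: a continuous (centred) day
    term, its square, and day-by-year interaction slopes.  Separation or
    rank deficiency is reported through flags, never raised.
    """
    import statsmodels.api as sm

    M, endog, names = _glm_design(table, X, list(covariates))
    rank_deficient = np.linalg.matrix_rank(M) < M.shape[1]
    glm = sm.GLM(endog, M, family=sm.families.Binomial())
    try:
        res = glm.fit(maxiter=200)
        params = dict(zip(names, res.params))
        bse = dict(zip(names, res.bse))
        converged = bool(res.converged) and np.all(np.isfinite(res.bse))
        llf = float(res.llf)
    except Exception:
        params = {n: np.nan for n in names}
        bse = {n: np.nan for n in names}
        converged = False
        llf = np.nan
        res = None
    if converged and max(abs(v) for v in params.values()) > 50:
        converged = False  # separation: runaway coefficients
    return GLMComparatorFit(params=params, bse=bse, converged=converged,
                            rank_deficient=bool(rank_deficient), llf=llf,
                            n_params=M.shape[1], result=res)


def compare_se(mixed_fits: Sequence[SARResults],
               glm_fits: Sequence[GLMComparatorFit],
               truth: ParameterSet,
               covariates: Sequence[str] | None = None) -> pd.DataFrame:
    """Paired estimate- and SE-comparison rows for the fixed effects.

    For each replicate and each of mu and the covariate coefficients:
    percent bias of the estimate under both model families and the two
    reported standard errors.  Pairs where either family failed are
    dropped.
    """
    if len(mixed_fits) != len(glm_fits):
        raise ValueError("need one GLM fit per mixed fit")
    rows = []
    for rep, (mf, gf) in enumerate(zip(mixed_fits, glm_fits)):
        if not (mf.converged and gf.converged):
            continue
        covs = covariates if covariates is not None else mf.spec.covariates
        names = ["mu"] + [f"beta:{c}" for c in covs]
        tvals = truth.to_dict(mf.spec)
        est_m = mf.params.to_dict(mf.spec)
        for name in names:
            tv = tvals[name]
            rows.append({
                "replicate": rep,
                "parameter": name,
                "truth": tv,
                "mixed_estimate": est_m[name],
                "glm_estimate": gf.params[name],
                "mixed_pct_bias": 100.0 * (est_m[name] - tv) / abs(tv),
                "glm_pct_bias": 100.0 * (gf.params[name] - tv) / abs(tv),
                "mixed_se": mf.se.get(name, np.nan),
                "glm_se": gf.bse[name],
            })
    df = pd.DataFrame(rows)
    if not df.empty:
        df["se_pct_diff"] = 100.0 * (df["mixed_se"] - df["glm_se"]) / df["glm_se"]
    return df


def run_se_comparison(scenario: ScenarioConfig | None = None,
                      replicates: int = 100, seed: int = 0,
                      truth: ParameterSet | None = None) -> pd.DataFrame:
    """Simulate from an AR-day + day/year-field truth; fit both families.

    Returns the :func:`compare_se` frame.  The default truth strengthens
    the latent processes (tau=0.9, rho=0.9, gamma=-0.45) in the direction
    of the wild-fish estimates, which is the regime where ignoring the
    latent uncertainty understates fixed-effect standard errors.
    """
    cfg = scenario if scenario is not None else desk_scenario(seed=seed)
    if truth is None:
        truth = cfg.params.replace(tau=0.9, psi=0.6, rho=0.9, gamma=-0.45,
                                   sigma=0.6)
    spec = cfg.spec
    gen_rng = np.random.default_rng(cfg.seed)
    n0 = generate_arrivals(cfg, gen_rng)
    X, _ = generate_covariates(cfg, gen_rng)
    ss = np.random.SeedSequence(seed)
    mixed, glms = [], []
    for child in ss.spawn(replicates):
        sim_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        table = simulate(truth, spec, n0, X, sim_seed, days=cfg.days,
                         years=np.asarray(cfg.years),
                         rear_type=cfg.rear_type)
        mixed.append(SARModel(table, X, spec).fit(start=truth))
        glms.append(fit_glm_comparator(table, X, spec.covariates))
    return compare_se(mixed, glms, truth, spec.covariates)


# ---------------------------------------------------------------------------
# discrimination and fit summaries
# ---------------------------------------------------------------------------

def auc(scores, outcomes) -> float:
    """ROC area via the Mann-Whitney statistic with midrank ties.

    ``scores`` are per-fish survival predictions, ``outcomes`` the 0/1
    adult-return indicators.  Invariant to strictly monotone transforms
    of the scores.  Errors if either class is empty.
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes).astype(bool)
    if scores.shape != outcomes.shape:
        raise ValueError("scores and outcomes must have the same shape")
    n_pos = int(outcomes.sum())
    n_neg = outcomes.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need both classes present")
    ranks = rankdata(scores)  # midranks
    rank_sum = float(ranks[outcomes].sum())
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def cell_auc(table: CohortTable, survival: np.ndarray) -> float:
    """AUC with every fish assigned its cohort cell's predicted survival.

    ``survival`` is the fitted (n_days, n_years) surface; fish in the
    same cell tie and are handled by midranks.
    """
    s = np.asarray(survival, dtype=float)
    if s.shape != table.shape:
        raise ValueError("survival surface does not match the lattice")
    obs = table.n > 0
    scores = np.repeat(s[obs], table.n[obs])
    outcomes = np.concatenate([
        np.r_[np.ones(k), np.zeros(n - k)]
        for n, k in zip(table.n[obs], table.k[obs])
    ])
    return auc(scores, outcomes)


def fitted_survival_surface(res: SARResults) -> np.ndarray:
    """Fitted s_jt surface of a converged mixed-model fit."""
    prob = res.model.problem
    return expit(eta_surface(res.params, res.re_modes, prob.x))


def deviance_ratio(loglik_m: float, loglik_null: float,
                   loglik_saturated: float | None = None,
                   convention: str = "saturated") -> float:
    """Proportional deviance reduction 1 - D_m / D_0.

    Under the primary ``"saturated"`` convention D is the deviance
    against the saturated model (one parameter per observed cell), so the
    ratio is 0 for the null model and 1 for a saturated fit.  The
    ``"raw"`` convention uses D = -2 logL directly, as sometimes printed
    alongside.
    """
    if convention == "saturated":
        if loglik_saturated is None:
            raise ValueError("saturated log likelihood required")
        d_m = 2.0 * (loglik_saturated - loglik_m)
        d_0 = 2.0 * (loglik_saturated - loglik_null)
    elif convention == "raw":
        d_m = -2.0 * loglik_m
        d_0 = -2.0 * loglik_null
    else:
        raise ValueError("convention must be 'saturated' or 'raw'")
    if d_0 == 0:
        raise ZeroDivisionError("null deviance is zero")
    return 1.0 - d_m / d_0


def deviance_table(data: CohortTable, fits: dict[str, SARResults]
                   ) -> pd.DataFrame:
    """Deviance-ratio table for a set of fits on the same data.

    Requires a fit labelled ``"null"``.  Both conventions are reported.
    """
    if "null" not in fits:
        raise KeyError("need a fit labelled 'null'")
    ll_sat = saturated_loglik(data)
    ll_null = fits["null"].llf
    rows = []
    for label, f in fits.items():
        rows.append({
            "model": label,
            "loglik": f.llf,
            "deviance_ratio": deviance_ratio(f.llf, ll_null, ll_sat),
            "deviance_ratio_raw": deviance_ratio(f.llf, ll_null,
                                                 convention="raw"),
        })
    return pd.DataFrame(rows)
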