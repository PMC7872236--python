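# Methods

## The model

`sarmix` estimates smolt-to-adult return (SAR) probabilities for cohorts
of PIT-tagged juvenile salmonids indexed by passage day *j* and
outmigration year *t*.  The observation model is binomial per lattice
cell,

    k_jt ~ Binomial(n_jt, s_jt),        s_jt = expit(eta_jt),

with a logistic link over fixed and latent effects

    eta_jt = mu + beta' x_t + nu_j + omega_t + xi_jt.

* `mu` — mean logit survival.
* `beta` — coefficients of standardised year-level marine covariates
  (columns of X; at most two per model, admissible pairs only).
* `nu_j` — stationary AR(1) day effect: lag-1 correlation `tau`,
  innovation sd `psi`, marginal variance `psi^2 / (1 - tau^2)`.
* `omega_t` — stationary AR(1) year effect with (`pi`, `phi`) likewise.
* `xi_jt` — separable AR(1)xAR(1) day-by-year field: within a year the
  day covariance is `Sigma[j, j+d] = sigma^2 rho^d / (1 - rho^2)`;
  across years the day-vector evolves as
  `xi_t ~ MVN(gamma xi_{t-1}, Sigma)`, initialised at its stationary law
  `MVN(0, Sigma / (1 - gamma^2))`.  Marginal cell variance:
  `sigma^2 / ((1 - rho^2)(1 - gamma^2))`.

At most two of the three latent components are active in any candidate
model; with all three active the day or year component collapses to
numerical zero and the model is not estimable, so the candidate space
uses the six one- and two-component configurations.

### Variance convention

AR(1) processes here are parameterised by their *innovation* standard
deviation (`psi`, `phi`, `sigma`) together with the lag-1 correlation;
the marginal (stationary) variance is `scale^2 / (1 - corr^2)`.  Reports
that quote "process error" quote the innovation sd.  This matches the
convention of the AR(1) density in TMB-style mixed-model software, and
it is the reading under which the within-year field covariance has
diagonal `sigma^2 / (1 - rho^2)`.  A useful identity used throughout:
with `M(c)` the tridiagonal matrix with diagonal
`[1, 1+c^2, ..., 1+c^2, 1]` and off-diagonal `-c`, the AR(1) precision
is `M(corr) / scale^2`, the field precision is
`kron(M(gamma), M(rho)) / sigma^2`, and `det M(c) = 1 - c^2` for every
dimension.  All prior log-determinants are therefore closed-form.

## Estimation

The marginal likelihood integrates the joint likelihood over the latent
vector `eps` by Laplace approximation:

    -log L(theta) ~= f(theta, eps_hat) + 1/2 log det H - (D/2) log 2 pi,

where `eps_hat` minimises the joint negative log likelihood `f` over
`eps` and `H = Q + A' W A` is the inner Hessian (prior precision plus
diagonal binomial curvature mapped through the 0/1 cell incidence).

* **Inner problem.** Damped Newton iterations with backtracking line
  search, warm-started across outer evaluations; convergence at
  `max |grad| <= 1e-8`.  `H` is positive definite in exact arithmetic
  (PD prior precision + PSD curvature); a tiny escalating jitter guards
  the factorisation numerically.
* **Outer problem.** L-BFGS-B over unconstrained transforms — `log` for
  the three scales, `atanh` for the four correlations — with wide box
  bounds (|atanh corr| <= 7, log scale in [-12, 4]) purely to keep
  iterates finite.  Gradients of the Laplace objective are analytic:
  the envelope theorem handles `f` at the mode; the prior log-dets are
  closed-form; `log det H` differentiates through the implicit mode via
  `d eps_hat/d theta = -H^{-1} (d^2 f / d eps d theta)` and trace
  identities evaluated with the dense inverse.  The gradient is verified
  against central finite differences in the test suite at 5e-4 relative
  tolerance (FD truncation dominates that gap).
* **Standard errors.** The outer Hessian is formed by central finite
  differences of the analytic gradient (step 1e-4 on the transformed
  scale); its inverse is mapped back through the transforms by the delta
  method.  Confidence intervals for parameters are normal on the
  transformed scale and mapped back, so they respect the domains.
* **Convergence.** A fit is converged iff the outer Hessian is positive
  definite and `max |gradient| <= 0.001`, the usual criterion in this
  model family.  Two further honesty guards flag non-convergence: a free
  parameter on its box bound (a variance collapsing to zero, a
  correlation running to +-1), and degenerate data (no survivors at all,
  or no mortalities), where `mu` diverges.  Non-converged fits are
  returned, never raised, and are excluded from model ranking.

All linear algebra is dense Cholesky.  The largest lattice the package
targets (91 days x 16 years with day + field components, ~1,550 latent
effects) factorises in ~0.1 s; larger problems would warrant a sparse
or blocked path, which is deliberately out of scope.

## Derived quantities

* Daily survival surfaces: `s_jt = expit(eta_hat_jt)` with pointwise
  intervals formed on the logit scale from the fixed-effect delta-method
  variance plus the conditional latent variance `diag(A H^{-1} A')`,
  then mapped through `expit` (hence always inside (0, 1)).  Cross
  terms between fixed-effect uncertainty and the latent modes are
  neglected, the standard empirical-Bayes simplification.
* Annual survival: arrival-weighted mean
  `S_t = sum_j n_jt s_jt / sum_j n_jt` with a delta-method variance that
  uses the full within-year latent covariance plus the (perfectly
  correlated within year) fixed-effect variance.
* Covariate effect curves: percent change of survival relative to
  `expit(mu)` along one standardised covariate, others at zero.
* Model selection: marginal AIC `2k - 2 log L` with `k` the number of
  estimated fixed-effect and variance/correlation parameters (latent
  modes are not counted; pinned parameters are not counted).  Akaike
  weights are `exp(-delta/2)` normalised over converged candidates;
  covariate importance sums weights over models containing a covariate,
  with a "blank" entry for covariate-free models.
* Deviance ratios `1 - D_m / D_0`: the primary convention measures
  deviance against the saturated model (one parameter per observed
  cell), giving 0 for the null fit and 1 for a saturated fit; the raw
  `-2 log L` convention is available alongside.
* AUC: Mann-Whitney with midrank ties; every fish carries its cohort
  cell's fitted survival (the only prediction unit the model defines),
  pooled over years.

## Synthetic data

The generator emulates the structure the analysis assumes, not any
particular river system:

* **Arrivals.** A discretised skew-normal kernel over the day window,
  allocated multinomially per year.  Wild preset: mode near day 123,
  long right tail past day 175, ~2,100 smolts/year (study-scale wild
  totals).  Hatchery preset: narrower, >= 95% of mass before day 160,
  ~15,700 smolts/year.
* **Covariates.** Yearly AR(1) series (default lag-1 correlation 0.3)
  sharing a common factor whose loading sets the expected
  cross-correlation (default 0.2); each series is also emitted as a
  monthly series whose in-season months average exactly back to the
  yearly value, so seasonal binning and standardisation can be tested
  end to end.
* **Survival.** Unconditional simulation from the model itself: latent
  processes drawn from their stationary laws, binomial outcomes per
  cell.  The truth record keeps the parameters and the realised latent
  fields.
* **Default truth (wild preset).** `mu = logit(0.009)`,
  `beta = (0.458, -0.608)`, `tau = 0.986`, `psi = 0.793`, `rho = 0.932`,
  `gamma = -0.489`, `sigma = 0.611` — anchored to wild-fish estimates of
  this model family at study scale.  The hatchery preset uses the
  field-only configuration with `mu = logit(0.008)`, `rho = 0.955`,
  `gamma = -0.067`, `sigma = 0.58`.

What the generator does *not* emulate: hydro-system passage routes,
transportation, region structure beyond a single label, fish size or
maturation, and covariate seasonality beyond a single season per
series.  Passing tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions, not robustness
to the misspecifications real detection data carry.

## Simulation experiments (desk scale)

The validation experiments default to a reduced lattice — 30 days x 8
years, 2,100 smolts/year, 100 replicates per trial — so that the full
three-by-three factorial (900 refits) runs in minutes on one CPU; the
study-scale lattice (91 x 16, 500 replicates) is a configuration change
(`ScenarioConfig` / `ExperimentDesign`).  On the reduced lattice the
base truth uses moderate correlations (`tau = 0.5`, `rho = gamma = 0.5`,
innovation sds 0.4-0.5): the strong study-scale correlations sit too
close to the boundary for a 30-day window to carry information about
them, and each experiment overrides the factor under study per trial
anyway (sample size 50% / 100% / 500%; `tau` in {0.1, 0.5, 0.9};
`rho = gamma` in {0.1, 0.5, 0.9}).

Recovery fits start at the generating parameters.  This is a runtime
choice, not a crutch: the optimum is start-independent (checked
explicitly in the suite by comparing neutral and truth starts), but the
warm start roughly halves the outer iterations across hundreds of
replicates.  Replicates whose fit fails the convergence criterion are
recorded and excluded from bias/precision summaries, with the
convergence rate reported alongside.

The SE-comparison experiment simulates from an AR-day + field truth
with strengthened correlations (`tau = 0.9`, `rho = 0.9`,
`gamma = -0.45`) — the regime of the wild-fish estimates, where a
fixed-effects GLM (day, day squared, day-by-year interaction slopes)
reports materially narrower fixed-effect standard errors than the mixed
model because it conditions away the latent-process uncertainty.

The GLM comparator codes day as a centred continuous regressor (in
decades of days, for conditioning), plus its square, plus day-by-year
product terms with the first year as baseline.  Percent differences for
parameters with truth at zero are reported as absolute differences and
flagged.

## Numerical choices and limitations

* Inner Newton tolerance 1e-8 (max gradient); outer L-BFGS-B `gtol`
  1e-6, `ftol` 1e-12; outer FD-Hessian step 1e-4.
* Laplace error on a binomial cell is O(1/information); the quadrature
  cross-check in the suite uses cell sizes ~1,000 where that error is
  below 1e-3.  At very small cell counts the approximation is cruder —
  the same caveat as for any Laplace-based mixed-model fit at low
  information.
* Day gaps: the day lattice is contiguous, so the field's day
  correlation at gap `d` is always realised through `d` lag-1 steps;
  empty cells (n = 0) contribute no likelihood but remain in the latent
  field through the prior.
* Interval calibration: pointwise 95% intervals for the daily surface
  achieve roughly 92% empirical coverage in the desk-scale simulation —
  the familiar mild undercoverage of plug-in empirical-Bayes intervals,
  which ignore variance-parameter uncertainty.
* Ties and degeneracies: non-PD outer Hessians, bound-touching
  parameters and degenerate outcome tables are reported as
  non-converged; in model scans such rows carry no delta-AIC and no
  weight.
* Leap years: day-of-year is the plain integer ordinal (non-leap
  labelling of dates); no calendar adjustment is attempted.
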