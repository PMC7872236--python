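# sarmix

Mixed-effects binomial modelling of **smolt-to-adult return (SAR)** for
out-migrating juvenile salmonids, on a day-of-year x year cohort lattice.

Marine survival of spring/summer Chinook salmon depends both on ocean
conditions in the year of entry and on *when* each fish arrives in the
estuary — a carryover effect of freshwater migration timing.  Fixed-effect
treatments of timing (a quadratic day term, independent year dummies)
ignore the autocorrelation of these processes and understate the
uncertainty of everything built on top of them.  `sarmix` is for
quantitative fisheries scientists who want the mixed-effects alternative:
latent autocorrelated processes for day, year and their interaction,
estimated jointly with marine-covariate effects.

## The model

For the cohort of `n_jt` smolts passing the indexing dam on day *j* of
year *t*, with `k_jt` detected again as adults:

    k_jt ~ Binomial(n_jt, s_jt)
    logit(s_jt) = mu + beta' x_t + nu_j + omega_t + xi_jt

* `x_t` — standardised year-level marine indices (upwelling, SST, gyre
  and ENSO indices, ...), binned to seasonal means; at most two per
  candidate model and only pairs with |r| < 0.7;
* `nu_j` — stationary AR(1) day effect (correlation `tau`, innovation sd
  `psi`);
* `omega_t` — stationary AR(1) year effect (`pi`, `phi`);
* `xi_jt` — separable AR(1) x AR(1) day-by-year Gaussian field: within-year
  day covariance `Sigma[j, j+d] = sigma^2 rho^d / (1 - rho^2)`, across-year
  AR(1) with correlation `gamma`.

The marginal likelihood integrates over the latent effects by Laplace
approximation (inner Newton on the latent modes, analytic outer
gradients); candidate models are ranked by marginal AIC, with Akaike
weights summarising covariate importance.  A fit is *converged* only
with a positive-definite Hessian and max |gradient| <= 0.001.
See `docs/methods.md` for the full account.

## Worked example

Everything runs on synthetic data generated by the package itself; no
downloads are needed.

```python
from sarmix import SARModel
from sarmix import synthetic

cfg = synthetic.desk_scenario(seed=42)      # 30 days x 8 years, wild preset
ds = synthetic.generate_dataset(cfg)        # cohorts + covariates + truth
res = SARModel(ds.table, ds.X, cfg.spec).fit()
print(res.summary())
```

```
SAR mixed-effects binomial model (wild, 100-129 x 2000-2007)
  covariates: env1.spr, env2.spr
  random components: day, dayyear
  log-marginal-likelihood -254.1856   AIC 524.3712   k=8
  max|gradient| 2.69e-05   PD Hessian: True   converged: True

  parameter                               estimate   std err
  mu (mean logit survival)                 -4.7758    0.2420
  beta[env1.spr]                            0.5671    0.1319
  beta[env2.spr]                           -0.7643    0.1482
  tau (day-effect correlation)              0.3714    0.3280
  psi (day-effect innovation sd)            0.4174    0.1870
  rho (day corr. of day/year field)         0.5853    0.1763
  pi (year corr. of day/year field)         0.5729    0.2423
  phi (day/year-field innovation sd)        0.4962    0.1359

  mean survival 0.0084 (95% CI 0.0052, 0.0134)
```

The generating truth here was `mu = logit(0.009) = -4.71`,
`beta = (0.458, -0.608)`, `tau = rho = gamma = 0.5`: every estimate
covers its truth well within two standard errors.  `mean survival` is
`expit(mu)` — survival at average covariates with latent effects at
zero.  Derived surfaces come from the results object:

```python
ann = res.annual_survival()                 # arrival-weighted S_t with CIs
print(ann.head(3).round(4).to_string(index=False))
```

```
 year  survival     se     lo     hi
 2000    0.0060 0.0022 0.0016 0.0103
 2001    0.0269 0.0078 0.0116 0.0422
 2002    0.0086 0.0030 0.0027 0.0145
```

`res.predict_daily_survival()` gives the day x year surface with
pointwise intervals, `res.covariate_effect_curve("env1.spr")` the percent
change in survival along a covariate, and `res.plot_*` the matching
figures.  Model scans use `sarmix.selection.enumerate_models` /
`fit_candidates`; the validation toolkit (parameter-recovery
experiments, the fixed-effects GLM comparator, AUC, deviance ratios)
lives in `sarmix.validation`.

A thin CLI covers the two shell-friendly tasks:

```sh
sarmix simulate --preset wild --seed 1 --out bundle/
sarmix fit --cohorts bundle/cohorts.csv --covariates bundle/covariates.csv \
           --covariate env1.spr --covariate env2.spr --random dayyear \
           --out fit.json
```

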