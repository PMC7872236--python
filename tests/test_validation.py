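"""Recovery experiments, the GLM comparator, AUC and deviance ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sarmix import CohortTable, ModelSpec, ParameterSet, SARModel
from sarmix import synthetic
from sarmix.likelihood import saturated_loglik
from sarmix.validation import (
    ExperimentDesign,
    auc,
    cell_auc,
    compare_se,
    deviance_ratio,
    deviance_table,
    fit_glm_comparator,
    fitted_survival_surface,
    run_recovery_experiment,
)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_constant_predictions(self):
        assert auc([0.3] * 6, [1, 0, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_matches_bruteforce_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=200)
        scores[rng.random(200) < 0.3] = scores[0]  # force ties
        outcomes = rng.random(200) < 0.4
        pos = scores[outcomes]
        neg = scores[~outcomes]
        wins = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        oracle = (wins + 0.5 * ties) / (pos.size * neg.size)
        assert auc(scores, outcomes) == pytest.approx(oracle, abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.uniform(size=300)
        outcomes = rng.random(300) < scores  # informative predictions
        assert auc(scores, outcomes) == pytest.approx(
            roc_auc_score(outcomes, scores), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=50)
        outcomes = np.r_[np.ones(10, bool), np.zeros(40, bool)]
        base = auc(scores, outcomes)
        assert auc(np.exp(scores), outcomes) == pytest.approx(base, abs=1e-12)
        assert auc(3 * scores - 7, outcomes) == pytest.approx(base, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_cell_expansion(self, desk_fit):
        s = fitted_survival_surface(desk_fit)
        a = cell_auc(desk_fit.model.data, s)
        assert 0.5 < a < 1.0  # informative but imperfect


class TestDevianceRatio:
    def test_null_is_zero_and_saturated_is_one(self, tiny_table):
        ll_sat = saturated_loglik(tiny_table)
        ll_null = -50.0
        assert deviance_ratio(ll_null, ll_null, ll_sat) == pytest.approx(0.0)
        assert deviance_ratio(ll_sat, ll_null, ll_sat) == pytest.approx(1.0)

    def test_monotone_in_nested_loglik(self, tiny_table):
        ll_sat = saturated_loglik(tiny_table)
        lls = [-60.0, -55.0, -52.0]  # nested fits: non-decreasing logL
        ratios = [deviance_ratio(ll, lls[0], ll_sat) for ll in lls]
        assert ratios == sorted(ratios)

    def test_raw_convention(self):
        assert deviance_ratio(-45.0, -50.0, convention="raw") == \
            pytest.approx(1.0 - 45.0 / 50.0)

    def test_table_on_fits(self, desk_dataset):
        ds, cfg = desk_dataset
        null = SARModel(ds.table, None, ModelSpec()).fit()
        full = SARModel(ds.table, ds.X, cfg.spec).fit(start=cfg.params)
        tab = deviance_table(ds.table, {"null": null, "full": full})
        r = tab.set_index("model")["deviance_ratio"]
        assert r["null"] == pytest.approx(0.0, abs=1e-12)
        assert 0 < r["full"] < 1


class TestGLMComparator:
    def test_matches_hand_rolled_irls_oracle(self, desk_dataset):
        ds, cfg = desk_dataset
        fit = fit_glm_comparator(ds.table, ds.X, cfg.spec.covariates)
        assert fit.converged and not fit.rank_deficient
        from sarmix.validation import _glm_design

        M, endog, names = _glm_design(ds.table, ds.X,
                                      list(cfg.spec.covariates))
        beta = _irls(M, endog)
        got = np.array([fit.params[n] for n in names])
        assert np.allclose(got, beta, atol=1e-6)

    def test_null_day_terms_when_no_day_structure(self):
        # simulate with no latent variance and no day trend: day and day^2
        # coefficients are within 2 SEs of zero
        from sarmix.model import simulate

        th = ParameterSet(mu=-3.0)
        n = np.full((20, 6), 500)
        table = simulate(th, ModelSpec(), n, None, 3)
        fit = fit_glm_comparator(table)
        for term in ("day", "day2"):
            assert abs(fit.params[term]) < 2 * fit.bse[term]

    def test_agrees_with_mixed_model_on_fixed_effects_data(self,
                                                           desk_dataset):
        # both families, fitted to the same data with no latent terms in
        # the mixed model and no day terms in the comparator, are the same
        # logistic regression
        import statsmodels.api as sm

        ds, cfg = desk_dataset
        spec = ModelSpec(covariates=cfg.spec.covariates)
        mixed = SARModel(ds.table, ds.X, spec).fit()
        obs = ds.table.n > 0
        jj, tt = np.nonzero(obs)
        x = ds.X.align(ds.table.years, spec.covariates)
        M = np.column_stack([np.ones(jj.size), x[tt, 0], x[tt, 1]])
        endog = np.column_stack([ds.table.k[jj, tt],
                                 (ds.table.n - ds.table.k)[jj, tt]])
        glm = sm.GLM(endog, M, family=sm.families.Binomial()).fit()
        assert mixed.params.mu == pytest.approx(glm.params[0], abs=1e-4)
        assert mixed.params.beta == pytest.approx(glm.params[1:], abs=1e-4)


def _irls(M, endog, tol=1e-12, maxit=100):
    """Independent IRLS oracle for binomial logistic regression."""
    k, nk = endog[:, 0], endog[:, 1]
    n = k + nk
    beta = np.zeros(M.shape[1])
    for _ in range(maxit):
        eta = M @ beta
        p = 1 / (1 + np.exp(-eta))
        w = n * p * (1 - p)
        z = eta + (k - n * p) / np.maximum(w, 1e-12)
        WM = M * w[:, None]
        new = np.linalg.solve(M.T @ WM, WM.T @ z)
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    return beta


class TestCompareSE:
    def test_identical_fits_give_zero_differences(self, desk_fit):
        from sarmix.validation import GLMComparatorFit

        truth = desk_fit.params
        spec = desk_fit.spec
        est = desk_fit.params.to_dict(spec)
        names = ["mu"] + [f"beta:{c}" for c in spec.covariates]
        glm = GLMComparatorFit(
            params={n: est[n] for n in names},
            bse={n: desk_fit.se[n] for n in names},
            converged=True, rank_deficient=False, llf=0.0, n_params=3)
        df = compare_se([desk_fit], [glm], truth)
        assert np.allclose(df["mixed_pct_bias"], df["glm_pct_bias"])
        assert np.allclose(df["se_pct_diff"], 0.0)

    def test_failed_pairs_are_dropped(self, desk_fit):
        from sarmix.validation import GLMComparatorFit

        glm = GLMComparatorFit(params={}, bse={}, converged=False,
                               rank_deficient=False, llf=np.nan, n_params=0)
        df = compare_se([desk_fit], [glm], desk_fit.params)
        assert df.empty


class TestRecoveryExperiment:
    def test_deterministic_given_seed(self):
        scenario = synthetic.desk_scenario(seed=31).replace(
            years=tuple(range(2000, 2005)), day_min=100, day_max=114,
            smolts_per_year=800)
        d = ExperimentDesign(experiment="day_corr", seed=11, replicates=1,
                             levels=(0.5,), scenario=scenario)
        s1 = run_recovery_experiment(d)
        s2 = run_recovery_experiment(d)
        pd.testing.assert_frame_equal(s1.frame, s2.frame)
        assert set(s1.frame["parameter"]) >= {"mu", "tau", "rho"}

    def test_experiment_levels_steer_the_truth(self):
        d = ExperimentDesign(experiment="field_corr", seed=1, replicates=1)
        t = d.truth_for(0.9)
        assert t.rho == 0.9 and t.gamma == 0.9
        d2 = ExperimentDesign(experiment="sample_size", seed=1, replicates=1)
        assert d2.truth_for(5.0).rho == d2.scenario.params.rho

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "design.yaml"
        p.write_text(
            "experiment: field_corr\nseed: 3\nreplicates: 2\n"
            "levels: [0.2, 0.5, 0.8]\n"
            "scenario: {seed: 4, smolts_per_year: 500}\n")
        d = ExperimentDesign.from_yaml(p)
        assert d.experiment == "field_corr"
        assert d.levels == (0.2, 0.5, 0.8)
        assert d.scenario.smolts_per_year == 500

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            ExperimentDesign(experiment="nope", seed=0)
        with pytest.raises(ValueError):
            ExperimentDesign(experiment="day_corr", seed=0, replicates=0)
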