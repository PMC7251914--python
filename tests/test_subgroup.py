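"""Covariate correction, DerSimonian-Laird pooling (with a textbook
oracle and a statsmodels cross-check), subgroup tables and typical
time-course simulation."""

import numpy as np
import pandas as pd
import pytest

from adprog.data import ArmObservation, StudyArm, TrialSet
from adprog.estimation import FitResult, ModelSpec, empirical_bayes
from adprog.model import CovariateEffect, PopulationParameters
from adprog.subgroup import (
    correct_estimates,
    pool_random_effects,
    subgroup_table,
    typical_time_course,
)


def make_fit_result(params: PopulationParameters) -> FitResult:
    spec = ModelSpec(placebo_form=params.placebo_form,
                     covariate_effects=params.covariate_effects)
    return FitResult(estimates=params, spec=spec, ofv=0.0, aic=0.0,
                     converged=True, message="synthetic", n_studies=1,
                     n_obs=1, n_params=spec.n_parameters)


def one_arm_ts(age, adas, study_id="S1"):
    return TrialSet(arms=[StudyArm(
        study_id, adas, age, 100, (ArmObservation(26.0, 1.0, 90),))])


FINAL_PARAMS = PopulationParameters(
    alpha_typ=0.112, beta_typ=-1.87, et50=7.99, delta=5.64,
    omega_alpha=0.148, omega_beta=0.725, rho=-0.717,
    covariate_effects=(
        CovariateEffect("baseline_adas", "alpha", "inverse_u", 1.53, ref=24.5),
        CovariateEffect("baseline_age", "alpha", "power", -2.17, ref=73.5),
    ))


class TestCorrectEstimates:
    def _ebe(self, alpha_i=0.174, se=0.01):
        return pd.DataFrame({
            "study_id": ["S1"], "eta_alpha": [0.0], "eta_beta": [0.0],
            "sd_eta_alpha": [0.1], "sd_eta_beta": [0.1],
            "alpha_i": [alpha_i], "beta_i": [-1.9],
            "se_alpha_i": [se], "se_beta_i": [0.2]})

    def test_reference_profile_passes_through(self):
        fr = make_fit_result(FINAL_PARAMS)
        out = correct_estimates(self._ebe(), one_arm_ts(73.5, 24.5), fr)
        assert out.alpha_star[0] == pytest.approx(out.alpha_i[0])
        assert out.beta_star[0] == pytest.approx(out.beta_i[0])

    def test_young_study_rescaled_by_power_factor(self):
        # age 60 at reference ADAS: factor (60/73.5)^-2.17 = 1.5533
        fr = make_fit_result(FINAL_PARAMS)
        out = correct_estimates(self._ebe(0.174), one_arm_ts(60.0, 24.5), fr)
        assert out.factor_alpha[0] == pytest.approx(1.5533, abs=1e-3)
        assert out.alpha_star[0] == pytest.approx(0.1120, abs=2e-4)
        assert out.se_alpha_star[0] == pytest.approx(0.01 / 1.5533, rel=1e-3)

    def test_correction_removes_age_trend(self, default_set, final_fit):
        ts, _ = default_set
        ebe = empirical_bayes(ts, final_fit)
        out = correct_estimates(ebe, ts, final_fit)
        ages = np.array([a.baseline_age for a in ts.arms])
        r_raw = np.corrcoef(out.alpha_i, ages)[0, 1]
        r_cor = np.corrcoef(out.alpha_star, ages)[0, 1]
        assert r_raw < -0.2
        assert abs(r_cor) < 0.15


class TestPooling:
    def test_identical_inputs_pool_to_themselves(self):
        pe = pool_random_effects([4.2, 4.2, 4.2], [0.3, 0.3, 0.3])
        assert pe.mean == pytest.approx(4.2)
        assert pe.tau2 == 0.0

    def test_textbook_dersimonian_laird_arithmetic(self):
        # hand-computed: w = 4 each, Q = 8, tau2 = (8-1)/4 = 1.75,
        # w* = 0.5 each, pooled = 6, SE = 1
        pe = pool_random_effects([5.0, 7.0], [0.5, 0.5])
        assert pe.mean == pytest.approx(6.0)
        assert pe.tau2 == pytest.approx(1.75)
        assert pe.ci_low == pytest.approx(6.0 - 1.96)
        assert pe.ci_high == pytest.approx(6.0 + 1.96)

    def test_matches_statsmodels_combine_effects(self):
        from statsmodels.stats.meta_analysis import combine_effects
        rng = np.random.default_rng(8)
        y = rng.normal(5, 1, size=12)
        se = rng.uniform(0.2, 0.8, size=12)
        pe = pool_random_effects(y, se)
        res = combine_effects(y, se**2, method_re="chi2")
        assert pe.tau2 == pytest.approx(res.tau2, rel=1e-6)
        frame = res.summary_frame()
        assert pe.mean == pytest.approx(
            frame.loc["random effect", "eff"], rel=1e-6)

    def test_single_estimate(self):
        pe = pool_random_effects([3.0], [0.5])
        assert (pe.mean, pe.tau2, pe.k) == (3.0, 0.0, 1)
        assert pe.ci_low == pytest.approx(3.0 - 1.96 * 0.5)

    def test_order_invariance(self):
        y = [4.0, 5.5, 6.1, 5.0]
        se = [0.3, 0.5, 0.4, 0.6]
        a = pool_random_effects(y, se)
        b = pool_random_effects(y[::-1], se[::-1])
        assert a.mean == pytest.approx(b.mean)
        assert a.tau2 == pytest.approx(b.tau2)

    def test_rejects_nonpositive_se(self):
        with pytest.raises(ValueError):
            pool_random_effects([1.0, 2.0], [0.5, 0.0])


class TestSubgroupTable:
    def test_annualization_consistency(self, default_set, final_fit):
        ts, _ = default_set
        ebe = empirical_bayes(ts, final_fit)
        tab = subgroup_table(ts, final_fit, ebe=ebe)
        overall = tab[tab.stratifier == "overall"].iloc[0]
        corr = correct_estimates(ebe, ts, final_fit)
        pe = pool_random_effects(corr.alpha_star * 52, corr.se_alpha_star * 52)
        assert overall.alpha_corr_year == pytest.approx(pe.mean, rel=1e-10)
        # corrected overall rate agrees with the typical annual rate
        assert overall.alpha_corr_year == pytest.approx(
            final_fit.estimates.alpha_typ * 52, rel=0.05)

    def test_ci_contains_mean_and_tau2_nonnegative(self, default_set, final_fit):
        ts, _ = default_set
        tab = subgroup_table(ts, final_fit)
        assert ((tab.alpha_corr_year_low <= tab.alpha_corr_year)
                & (tab.alpha_corr_year <= tab.alpha_corr_year_high)).all()
        assert (tab.alpha_corr_tau2 >= 0).all()
        assert (tab.k >= 1).all()

    def test_built_in_region_effect_detected(self):
        # generator-side East-Asia slowdown (x0.93 on alpha): shrinkage
        # of the per-study estimates attenuates the shift, so with ~5
        # East-Asian studies per replicate single-replicate ordering is
        # unreliable; aggregated over replicates the corrected East-Asia
        # rate must sit below the other regions'
        from adprog.estimation import final_model_spec, fit, empirical_bayes
        from adprog.simulate import default_config, generate_trial_set
        diffs = []
        n_rep = 20
        for r in range(n_rep):
            cfg = default_config(seed=6000 + r).replace(
                region_alpha_multipliers={"EastAsia": 0.93})
            ts, _ = generate_trial_set(cfg)
            fr = fit(ts, final_model_spec(ts), n_restarts=1, seed=r,
                     compute_se=False)
            corr = correct_estimates(empirical_bayes(ts, fr), ts, fr)
            regions = np.array([a.region for a in ts.arms])
            vals = corr.alpha_star.to_numpy() * 52
            # pair within the replicate so global-estimate wobble cancels
            diffs.append(vals[regions == "EastAsia"].mean()
                         - vals[regions != "EastAsia"].mean())
        assert np.mean(diffs) < 0


class TestTypicalTimeCourse:
    def test_zero_at_baseline_with_zero_width_ci(self):
        tc = typical_time_course(5.82, -1.87, horizon_weeks=52,
                                 alpha_se_per_year=0.1, beta_se=0.1)
        first = tc.iloc[0]
        assert first.time_weeks == 0.0
        assert first.typical == 0.0
        assert first.ci_low == first.ci_high == 0.0

    def test_six_month_subgroup_profiles(self):
        east = typical_time_course(5.45, -2.43, times=[26.0])
        north = typical_time_course(6.11, -1.50, times=[26.0])
        assert round(float(east.typical[0]), 1) == 0.9
        assert round(float(north.typical[0]), 2) == 1.91

    def test_invalid_horizon(self):
        with pytest.raises(ValueError):
            typical_time_course(5.82, -1.87, horizon_weeks=0.0)
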