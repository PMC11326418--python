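"""Trajectory models: candidate families, Akaike weights, voxel-wise
age effects, Bonferroni thresholds, fitted stacks and rate maps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from infantflow import trajectory
from infantflow.trajectory import (EffectMap, akaike_weights,
                                   bonferroni_threshold, fit_candidate_models,
                                   fit_log_model, predict_map_stack, rate_maps,
                                   voxelwise_age_effects)


class TestAkaikeWeights:
    def test_two_model_example(self):
        w = akaike_weights([100.0, 102.0])
        assert w == pytest.approx([0.7311, 0.2689], abs=5e-5)

    def test_three_model_example(self):
        # deltas 0, 2, 4: weights are e^{0,-1,-2} normalised,
        # i.e. (1, 0.36788, 0.13534) / 1.50321
        w = akaike_weights([10.0, 12.0, 14.0])
        assert w == pytest.approx([0.66524, 0.24473, 0.09003], abs=5e-5)

    def test_equal_aics_give_equal_weights(self):
        assert akaike_weights([7.0, 7.0, 7.0]) == pytest.approx([1 / 3] * 3)

    def test_sum_one_and_shift_invariance(self):
        rng = np.random.default_rng(0)
        aic = rng.uniform(50, 150, 6)
        w = akaike_weights(aic)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(w, akaike_weights(aic + 1234.5))
        assert np.all(np.argsort(aic) == np.argsort(-w))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights([])


class TestCandidateFamilies:
    def test_aic_identity_holds_exactly(self):
        rng = np.random.default_rng(1)
        age = np.sort(rng.uniform(1.4, 28, 60))
        y = 16 * np.log(age) + rng.normal(0, 5, 60)
        res = fit_candidate_models(age, y)
        for fit in res.fits.values():
            assert fit.aic == -2.0 * fit.llf + 2.0 * fit.k

    def test_zero_noise_recovery_per_family(self):
        age = np.linspace(1.5, 27.5, 80)
        cases = {
            "linear": 2.0 * age + 5.0,
            "logarithmic": 16.38 * np.log(age) + 16.85,
            "quadratic": 30 + 3 * age - 0.05 * age**2,
            "exponential": 20.0 * np.exp(0.06 * age),
        }
        for family, y in cases.items():
            res = fit_candidate_models(age, y, families=[family])
            fit = res.fits[family]
            assert fit.r == pytest.approx(1.0, abs=1e-8)
            if family == "logarithmic":
                assert fit.params["intercept"] == pytest.approx(16.85, abs=1e-8)
                assert fit.params["log_age"] == pytest.approx(16.38, abs=1e-8)
            if family == "exponential":
                assert fit.params["a"] == pytest.approx(20.0, rel=1e-6)
                assert fit.params["b_age"] == pytest.approx(0.06, rel=1e-6)

    def test_poisson_recovers_log_link_coefficient(self):
        age = np.linspace(1.5, 27.5, 90)
        y = np.exp(3.0 + 0.05 * age)
        res = fit_candidate_models(age, y, families=["poisson"])
        assert res.fits["poisson"].params["age"] == pytest.approx(0.05, abs=1e-6)

    def test_single_model_weight_is_one(self):
        age = np.linspace(2, 27, 40)
        y = 2 * age + np.random.default_rng(2).normal(0, 3, 40)
        res = fit_candidate_models(age, y, families=["linear"])
        assert res.weights["linear"] == pytest.approx(1.0)

    def test_weights_sum_to_one_and_best_family(self, global_log_cohort):
        syn = global_log_cohort
        res = fit_candidate_models(syn.ages,
                                   syn.cohort_table["global_cbf"].to_numpy())
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert res.delta_aic.min() == 0.0
        assert res.best_family in ("logarithmic", "quadratic")
        summary = res.summary()
        assert list(summary.columns) == ["loglik", "k", "AIC", "BIC", "r",
                                         "dAIC", "wAIC"]

    def test_nonpositive_age_rejected_for_log(self):
        with pytest.raises(ValueError):
            fit_candidate_models(np.array([0.0, 1, 2, 3, 4, 5, 6]),
                                 np.arange(7.0), families=["logarithmic"])


class TestLogModel:
    def test_zero_noise_recovers_coefficients(self):
        age = np.linspace(1.4, 28, 76)
        y = 16.38 * np.log(age) + 16.85
        fit = fit_log_model(age, y)
        assert fit.params["log_age"] == pytest.approx(16.38, abs=1e-8)
        assert fit.params["intercept"] == pytest.approx(16.85, abs=1e-8)
        assert fit.r == pytest.approx(1.0)

    def test_null_age_effect_small_z(self):
        rng = np.random.default_rng(3)
        zs = []
        for _ in range(50):
            age = np.sort(rng.uniform(1.4, 28, 60))
            y = rng.normal(50, 8, 60)
            zs.append(fit_log_model(age, y).z)
        assert abs(np.mean(zs)) < 0.4

    def test_z_matches_probit_oracle(self):
        # the Bonferroni pairing: two-tailed p = 3.47e-7 <-> Z ~ 5.1
        z = trajectory.signed_z_from_p(3.47e-7, beta=1.0)
        assert z == pytest.approx(5.10, abs=0.01)
        assert trajectory.signed_z_from_p(3.47e-7, beta=-1.0) == pytest.approx(
            -5.10, abs=0.01)

    def test_covariates_adjusted(self):
        rng = np.random.default_rng(4)
        age = np.sort(rng.uniform(1.4, 28, 80))
        sex = rng.integers(0, 2, 80)
        y = 10 * np.log(age) + 6.0 * sex + rng.normal(0, 1, 80)
        fit = fit_log_model(age, y, covariates=pd.DataFrame({"sex": sex}))
        assert fit.params["log_age"] == pytest.approx(10.0, abs=0.3)
        assert fit.params["sex"] == pytest.approx(6.0, abs=0.5)

    def test_collinear_design_rejected(self):
        age = np.linspace(2, 27, 30)
        with pytest.raises(ValueError, match="collinear"):
            fit_log_model(age, np.log(age),
                          covariates=pd.DataFrame({"dup": np.log(age)}))


class TestBonferroni:
    def test_paper_scale_thresholds(self):
        out = bonferroni_threshold(0.05, 144237)
        assert out["p_threshold"] == pytest.approx(3.47e-7, abs=5e-10)
        assert round(out["z_threshold"], 1) == 5.1

    def test_trivial_and_domain_counts(self):
        out = bonferroni_threshold(0.05, 1)
        assert out["p_threshold"] == 0.05
        assert out["z_threshold"] == pytest.approx(1.96, abs=5e-3)
        assert bonferroni_threshold(0.05, 3)["p_threshold"] == pytest.approx(
            0.0167, abs=5e-5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestVoxelwise:
    def test_matches_per_voxel_fit(self):
        rng = np.random.default_rng(5)
        age = np.sort(rng.uniform(1.4, 28, 50))
        covs = pd.DataFrame({"sex": rng.integers(0, 2, 50),
                             "motion": rng.uniform(0.05, 0.5, 50)})
        data = rng.normal(50, 10, (12, 50)) + \
            np.outer(rng.uniform(5, 20, 12), np.log(age))
        em = voxelwise_age_effects(data, age, covariates=covs)
        for v in [0, 7, 11]:
            single = fit_log_model(age, data[v], covariates=covs)
            assert em.beta[v] == pytest.approx(single.params["log_age"])
            assert em.z[v] == pytest.approx(single.z, abs=1e-9)
            assert em.r[v] == pytest.approx(single.r, abs=1e-9)

    def test_null_type_one_calibration(self):
        rng = np.random.default_rng(6)
        age = np.sort(rng.uniform(1.4, 28, 76))
        data = rng.normal(50, 10, (4000, 76))
        em = voxelwise_age_effects(data, age)
        rate = np.mean(np.abs(em.z) > 1.96)
        assert 0.03 < rate < 0.07

    def test_constant_voxel_flagged_with_zero_z(self):
        age = np.linspace(2, 27, 30)
        data = np.vstack([np.full(30, 42.0), 8 * np.log(age)])
        em = voxelwise_age_effects(data, age)
        assert em.degenerate[0] and not em.degenerate[1]
        assert em.z[0] == 0.0

    def test_recovers_cluster_beta_ordering(self, regional_cohort):
        syn = regional_cohort
        covs = pd.DataFrame({"sex": syn.cohort_table["sex"],
                             "motion": syn.cohort_table["mrd_mm"]})
        em = voxelwise_age_effects(syn.data_matrix(), syn.ages, covariates=covs,
                                   mask=syn.mask)
        labels = syn.truth_labels[syn.mask]
        # frontoparietal keeps rising longest -> largest log-age slope
        beta_fp = em.beta[labels == 2].mean()
        beta_sm = em.beta[labels == 1].mean()
        assert beta_fp > beta_sm


class TestStackAndRates:
    def _simple_effects(self):
        age = np.linspace(1.4, 28, 76)
        data = np.vstack([16.38 * np.log(age) + 16.85,
                          10.0 * np.log(age) + 30.0])
        return voxelwise_age_effects(data, age)

    def test_prediction_at_age_one_is_intercept(self):
        em = self._simple_effects()
        stack = predict_map_stack(em, ages=[1.0])
        assert stack.maps[0, 0] == pytest.approx(16.85, abs=1e-8)
        assert stack.maps[0, 1] == pytest.approx(30.0, abs=1e-8)

    def test_default_grid_has_55_ages(self):
        em = self._simple_effects()
        stack = predict_map_stack(em)
        assert len(stack) == 55
        assert stack.ages[0] == 1.0 and stack.ages[-1] == 28.0

    def test_predictions_monotone_for_positive_beta(self):
        em = self._simple_effects()
        stack = predict_map_stack(em)
        assert np.all(np.diff(stack.maps[:, 0]) > 0)

    def test_sex_and_motion_settings_used(self):
        rng = np.random.default_rng(8)
        age = np.sort(rng.uniform(1.4, 28, 60))
        covs = pd.DataFrame({"sex": rng.integers(0, 2, 60),
                             "motion": rng.uniform(0.1, 0.4, 60)})
        data = (12 * np.log(age) + 20 + 4 * covs["sex"].to_numpy()
                + 10 * covs["motion"].to_numpy())[None, :]
        em = voxelwise_age_effects(data, age, covariates=covs)
        stack = predict_map_stack(em, ages=[10.0])
        want = 12 * np.log(10) + 20 + 4 * 0.5 + 10 * 0.22
        assert stack.maps[0, 0] == pytest.approx(want, abs=1e-6)

    def test_invalid_age_rejected(self):
        em = self._simple_effects()
        with pytest.raises(ValueError):
            predict_map_stack(em, ages=[0.0])
        with pytest.raises(ValueError):
            rate_maps(em, [0.0])

    def test_rate_is_beta_over_age(self):
        em = self._simple_effects()
        rates = rate_maps(em, [6.0, 12.0])
        assert rates[1, 0] == pytest.approx(16.38 / 12.0)  # 1.365
        assert rates[0, 0] == pytest.approx(2 * rates[1, 0])
        assert rates[0, 1] == pytest.approx(10.0 / 6.0)
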