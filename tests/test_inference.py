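"""Degrees-of-freedom corrections, bootstrap, LRT, two-step, selector."""

import numpy as np
import pytest
from scipy import stats

import hetcrt
from hetcrt.inference import (apply_test, between_within_df, lrt_global,
                              parametric_bootstrap_test, residual_cluster_df,
                              select_correction, two_step_test, wald_t_test,
                              TestResult)


class TestResidualClusterDf:
    @pytest.mark.parametrize("n,q,expected", [(12, 2, 10), (50, 2, 48), (12, 3, 9)])
    def test_values(self, n, q, expected):
        assert residual_cluster_df(n, q) == expected

    def test_mask_input(self):
        assert residual_cluster_df(12, np.array([True, True, False, False])) == 10

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            residual_cluster_df(2, 2)


class TestBetweenWithinDf:
    @pytest.fixture(scope="class")
    def fit12(self):
        d = hetcrt.simulate_trial(hetcrt.make_scenario(3, "gaussian", 12, "fixed"), 4)
        return hetcrt.LinearMixedModel(d, "intercept").fit()

    def test_classical_within_classification(self, fit12):
        # M=1200, N=12, within columns = gr and trt:gr
        assert between_within_df(fit12, "trt:gr[1]",
                                 interaction_as="within") == 1200 - 12 - 2
        assert between_within_df(fit12, "gr[1]",
                                 interaction_as="within") == 1200 - 12 - 2
        assert between_within_df(fit12, "trt", interaction_as="within") == 12 - 2

    def test_default_assigns_interaction_the_between_df(self, fit12):
        # trt:gr inherits the cluster-level class: q_between = 3
        assert between_within_df(fit12, "trt:gr[1]") == 12 - 3
        assert between_within_df(fit12, "gr[1]") == 1200 - 12 - 1

    def test_multi_coefficient_contrast_rejected(self, fit12):
        with pytest.raises(ValueError, match="single"):
            between_within_df(fit12, np.array([1.0, 1.0, 0.0, 0.0]))

    def test_size_one_clusters_rejected(self):
        import pandas as pd
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"cluster_id": np.arange(20),
                              "trt": np.tile([0, 1], 10),
                              "gr": rng.integers(0, 2, 20),
                              "y": rng.normal(size=20)})
        fit = hetcrt.ClusterGEE(frame, "gaussian").fit()
        with pytest.raises(ValueError, match="size 1"):
            between_within_df(fit, "gr[1]")

    def test_df_ordering_on_study_designs(self, fit12):
        """Residual-cluster df never exceeds the classical within df on the
        study's designs (M - N - q_w >= N - q_b there)."""
        rc = residual_cluster_df(12, 2)
        bw = between_within_df(fit12, "trt:gr[1]", interaction_as="within")
        assert rc <= bw


class TestWaldT:
    @pytest.fixture(scope="class")
    def lmm_fit(self, scenario1_gauss_data):
        return hetcrt.LinearMixedModel(scenario1_gauss_data, "maximal").fit()

    def test_large_df_reproduces_z(self, lmm_fit):
        t = wald_t_test(lmm_fit, "trt:gr[1]", "residual_cluster", n_clusters=10 ** 7)
        z = wald_t_test(lmm_fit, "trt:gr[1]", "asymptotic_z")
        assert t.p_value == pytest.approx(z.p_value, abs=1e-5)

    def test_sign_symmetry(self, lmm_fit):
        c = lmm_fit.contrast_vector("trt:gr[1]")
        a = wald_t_test(lmm_fit, c, "residual_cluster")
        b = wald_t_test(lmm_fit, -c, "residual_cluster")
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_incompatible_pairings_rejected(self, scenario3_count_data, lmm_fit):
        gee = hetcrt.ClusterGEE(scenario3_count_data, "poisson").fit()
        with pytest.raises(ValueError):
            wald_t_test(gee, "trt:gr[1]", "satterthwaite")
        with pytest.raises(ValueError):
            wald_t_test(lmm_fit, "trt:gr[1]", "fay_graubard")
        with pytest.raises(ValueError):
            wald_t_test(lmm_fit, "trt:gr[1]", "no_such_method")

    def test_reject_flag_tracks_p(self, lmm_fit):
        res = wald_t_test(lmm_fit, "trt:gr[1]", "residual_cluster")
        assert res.reject_at_005 == (res.p_value < 0.05)


class TestLrt:
    def test_statistic_floored_at_zero_gives_p_one(self, six_cluster_frame):
        import dataclasses
        full = hetcrt.LinearMixedModel(six_cluster_frame, "intercept").fit("ML")
        null = hetcrt.LinearMixedModel(six_cluster_frame, "intercept",
                                       include_interaction=False).fit("ML")
        # a full fit that gains nothing (to optimizer tolerance) is clamped
        tied = dataclasses.replace(full, llf=null.llf - 1e-6)
        res = lrt_global(tied, null)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_three_level_subgroup_gets_two_df(self):
        spec = hetcrt.ScenarioSpec(
            scenario_id="custom", family_spec=hetcrt.FamilySpec("gaussian", 0.8),
            fixed=hetcrt.FixedEffects(0.0, 0.5, (0.3, 0.15), (0.0, 0.0)),
            ranef=hetcrt.RandomEffectSpec("common_intercept", sigma2=0.2),
            n_clusters=10, cluster_sizes=30, subgroup_probs=(1/3, 1/3, 1/3))
        d = hetcrt.simulate_trial(spec, 6)
        full = hetcrt.LinearMixedModel(d, "intercept").fit("ML")
        null = hetcrt.LinearMixedModel(d, "intercept",
                                       include_interaction=False).fit("ML")
        res = lrt_global(full, null)
        assert res.df == 2
        assert res.statistic >= 0
        assert res.p_value == pytest.approx(stats.chi2.sf(res.statistic, 2))

    def test_reml_fits_rejected(self, six_cluster_frame):
        full = hetcrt.LinearMixedModel(six_cluster_frame, "intercept").fit("REML")
        null = hetcrt.LinearMixedModel(six_cluster_frame, "intercept",
                                       include_interaction=False).fit("REML")
        with pytest.raises(ValueError, match="ML"):
            lrt_global(full, null)

    def test_non_nesting_rejected(self, six_cluster_frame):
        null = hetcrt.LinearMixedModel(six_cluster_frame, "intercept",
                                       include_interaction=False).fit("ML")
        with pytest.raises(ValueError):
            lrt_global(null, null)


class TestBootstrap:
    @pytest.fixture(scope="class")
    def small_fit(self):
        spec = hetcrt.ScenarioSpec(
            scenario_id="custom", family_spec=hetcrt.FamilySpec("gaussian", 0.8),
            fixed=hetcrt.FixedEffects(0.0, 0.5, (0.3,), (0.0,)),
            ranef=hetcrt.RandomEffectSpec("common_intercept", sigma2=0.3),
            n_clusters=8, cluster_sizes=25)
        d = hetcrt.simulate_trial(spec, 12)
        return hetcrt.LinearMixedModel(d, "intercept").fit()

    def test_deterministic_given_seed(self, small_fit):
        a = parametric_bootstrap_test(small_fit, B=20, seed=5)
        b = parametric_bootstrap_test(small_fit, B=20, seed=5)
        assert a.ci == b.ci
        c = parametric_bootstrap_test(small_fit, B=20, seed=6)
        assert a.ci != c.ci

    def test_ci_based_decision(self, small_fit):
        res = parametric_bootstrap_test(small_fit, B=30, seed=1)
        assert res.p_value is None and res.ci is not None
        assert res.reject_at_005 == (not res.ci[0] <= 0 <= res.ci[1])
        assert res.extras["B"] == 30

    def test_strong_effect_rejects(self):
        spec = hetcrt.ScenarioSpec(
            scenario_id="custom", family_spec=hetcrt.FamilySpec("gaussian", 0.8),
            fixed=hetcrt.FixedEffects(0.0, 0.5, (0.3,), (2.0,)),
            ranef=hetcrt.RandomEffectSpec("common_intercept", sigma2=0.05),
            n_clusters=12, cluster_sizes=60)
        d = hetcrt.simulate_trial(spec, 3)
        fit = hetcrt.LinearMixedModel(d, "intercept").fit()
        res = parametric_bootstrap_test(fit, B=30, seed=2)
        assert res.reject_at_005

    def test_simulated_design_preserved(self, small_fit):
        from hetcrt.inference import simulate_from_fit
        rng = np.random.default_rng(0)
        sim = simulate_from_fit(small_fit, rng)
        orig = small_fit.model.frame
        assert sim[["cluster_id", "trt", "gr"]].equals(orig[["cluster_id", "trt", "gr"]])
        assert not sim["y"].equals(orig["y"])


class TestTwoStep:
    def test_well_separated_covariance_keeps_maximal(self, scenario1_gauss_data):
        res, fit2, fb = two_step_test(scenario1_gauss_data, "gaussian",
                                      "residual_cluster", "residual_cluster")
        assert not res.used_fallback
        assert fb is None
        direct = wald_t_test(hetcrt.LinearMixedModel(
            scenario1_gauss_data, "maximal").fit(), "trt:gr[1]", "residual_cluster")
        assert res.p_value == pytest.approx(direct.p_value, abs=1e-12)

    def test_boundary_truth_triggers_fallback(self):
        spec = hetcrt.ScenarioSpec(
            scenario_id="custom", family_spec=hetcrt.FamilySpec("gaussian", 0.8),
            fixed=hetcrt.FixedEffects(0.0, 0.5, (0.3,), (0.0,)),
            ranef=hetcrt.RandomEffectSpec(
                "subgroup_specific", Sigma=np.array([[0.3, 0.3], [0.3, 0.3]])),
            n_clusters=20, cluster_sizes=40)
        used = 0
        for seed in range(3):
            d = hetcrt.simulate_trial(spec, seed)
            res, _, _ = two_step_test(d, "gaussian")
            used += res.used_fallback
        assert used >= 2  # rank-one truth: the slope variance estimate sits at 0

    def test_result_invariant_reject_consistency(self, scenario3_count_data):
        res, _, _ = two_step_test(scenario3_count_data, "poisson",
                                  "between_within", "residual_cluster")
        assert isinstance(res, TestResult)
        assert res.reject_at_005 == (res.p_value < 0.05)


class TestSelectCorrection:
    @pytest.mark.parametrize("true,fitted,family,expected", [
        ("glmm2", "glmm2", "gaussian", "satterthwaite"),
        ("glmm2", "glmm2", "poisson", "between_within"),
        ("glmm2", "glmm2", "bernoulli", "residual_cluster"),
        ("glmm2", "glmm", "gaussian", "satterthwaite"),
        ("glmm2", "glmm", "poisson", "residual_cluster"),
        ("glmm2", "glmm", "bernoulli", "residual_cluster"),
        ("glmm", "glmm2", "gaussian", "satterthwaite"),
        ("glmm", "glmm2", "poisson", "bootstrap"),
        ("glmm", "glmm2", "bernoulli", "bootstrap"),
        ("glmm", "glmm", "gaussian", "satterthwaite"),
        ("glmm", "glmm", "poisson", "between_within"),
        ("glmm", "glmm", "bernoulli", "between_within"),
        ("glmm", "gee", "poisson", "fay_graubard"),
        ("glmm2", "gee", "gaussian", "fay_graubard"),
    ])
    def test_selection_table(self, true, fitted, family, expected):
        assert select_correction(true, fitted, family) == expected

    def test_unknown_pairing_rejected(self):
        with pytest.raises(ValueError):
            select_correction("glmm3", "glmm", "poisson")


class TestApplyTest:
    def test_bootstrap_routes_through_dispatch(self, six_cluster_frame):
        fit = hetcrt.LinearMixedModel(six_cluster_frame, "intercept").fit()
        res = apply_test(fit, "trt:gr[1]", "bootstrap", seed=3, B=20)
        assert res.method == "bootstrap" and res.ci is not None
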