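"""Scenario presets and the trial simulator."""

import numpy as np
import pytest

import hetcrt
from hetcrt.scenarios import ConfigurationError, VARYING_SIZES


class TestPresets:
    @pytest.mark.parametrize("family,sigma,betas", [
        ("gaussian", [[0.2, 0.13], [0.13, 0.1]], (0.0, 0.5, 0.3, 0.0)),
        ("poisson", [[0.5, 0.25], [0.25, 0.5]], (-1.0, -0.07, -0.5, 0.0)),
        ("bernoulli", [[0.25, 0.18], [0.18, 0.5]], (-1.66, -0.32, -0.08, 0.0)),
    ])
    def test_scenario1_cells(self, family, sigma, betas):
        spec = hetcrt.make_scenario(1, family, 50, "fixed")
        assert np.allclose(spec.ranef.Sigma, sigma)
        assert np.allclose(spec.fixed.as_vector(), betas)
        assert spec.cluster_sizes == 100
        if family == "gaussian":
            assert spec.family_spec.residual_sd ** 2 == pytest.approx(0.64)

    def test_scenario2_downscales_variances_keeping_correlation(self):
        s1 = hetcrt.make_scenario(1, "poisson", 100, "fixed")
        s2 = hetcrt.make_scenario(2, "poisson", 100, "fixed")
        assert np.allclose(s2.ranef.Sigma, 0.1 * s1.ranef.Sigma)
        c1 = s1.ranef.Sigma[0, 1] / np.sqrt(s1.ranef.Sigma[0, 0] * s1.ranef.Sigma[1, 1])
        c2 = s2.ranef.Sigma[0, 1] / np.sqrt(s2.ranef.Sigma[0, 0] * s2.ranef.Sigma[1, 1])
        assert c1 == pytest.approx(c2)
        assert np.allclose(s2.ranef.Sigma, [[0.05, 0.025], [0.025, 0.05]])

    def test_scenario4_common_intercept(self):
        spec = hetcrt.make_scenario(4, "bernoulli", 12, "varying")
        assert spec.ranef.structure == "common_intercept"
        assert spec.ranef.sigma2 == pytest.approx(0.5)
        assert np.allclose(spec.fixed.as_vector(), (-1.66, -0.32, -0.08, 0.0))
        assert spec.cluster_sizes == VARYING_SIZES
        assert hetcrt.make_scenario(4, "gaussian", 50, "fixed").ranef.sigma2 \
            == pytest.approx(0.2)

    def test_scenario5_three_levels(self):
        spec = hetcrt.make_scenario(5, "gaussian", 50, "fixed")
        assert spec.n_levels == 3
        assert spec.subgroup_probs == pytest.approx((1 / 3, 1 / 3, 1 / 3))
        assert np.allclose(spec.fixed.as_vector(), (0, 0.5, 0.3, 0.15, 0, 0))
        assert spec.true_model == "glmm"

    def test_scenario6_arm_heterogeneous(self):
        spec = hetcrt.make_scenario(6, "bernoulli", 50, "fixed")
        # binary shares the count covariance; control arm scaled by 1.4
        assert np.allclose(spec.ranef.Sigma, [[0.5, 0.25], [0.25, 0.5]])
        assert np.allclose(spec.ranef.covariance(2, arm=0), 1.4 * spec.ranef.Sigma)
        assert np.allclose(spec.ranef.covariance(2, arm=1), spec.ranef.Sigma)

    def test_scenario7_nonnull_interaction(self):
        for fam, bmod in [("gaussian", 0.2), ("poisson", 0.1), ("bernoulli", 0.15)]:
            spec = hetcrt.make_scenario(7, fam, 50, "fixed")
            assert spec.fixed.beta_mod == (bmod,)

    @pytest.mark.parametrize("args", [
        (1, "gaussian", 12, "fixed"),     # N not in the scenario layout
        (1, "gaussian", 50, "varying"),
        (8, "gaussian", 50, "fixed"),     # no such preset
        (3, "negbin", 12, "fixed"),       # unknown family
    ])
    def test_unknown_cells_raise_configuration_errors(self, args):
        with pytest.raises(ConfigurationError):
            hetcrt.make_scenario(*args)

    def test_spec_yaml_roundtrip(self, tmp_path):
        spec = hetcrt.make_scenario(6, "poisson", 12, "varying")
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        back = hetcrt.ScenarioSpec.from_yaml(path)
        assert np.allclose(back.ranef.Sigma, spec.ranef.Sigma)
        assert back.fixed == spec.fixed
        assert back.cluster_sizes == spec.cluster_sizes
        assert back.ranef.arm_scale == spec.ranef.arm_scale


class TestRandomizationAndSizes:
    @pytest.mark.parametrize("n", [12, 50])
    def test_one_to_one_allocation(self, n):
        arms = hetcrt.randomize_clusters(n, 5)
        assert arms.sum() == n // 2
        assert np.array_equal(arms, hetcrt.randomize_clusters(n, 5))

    def test_odd_clusters_rejected(self):
        with pytest.raises(ValueError):
            hetcrt.randomize_clusters(13, 0)

    def test_fixed_sizes_constant(self):
        spec = hetcrt.make_scenario(1, "gaussian", 50, "fixed")
        assert np.array_equal(hetcrt.assign_cluster_sizes(spec), np.full(50, 100))

    def test_varying_sizes_cycle_the_pool(self):
        spec = hetcrt.make_scenario(3, "poisson", 12, "varying")
        sizes = hetcrt.assign_cluster_sizes(spec)
        assert np.array_equal(sizes, np.tile(VARYING_SIZES, 3)[:12])

    def test_size_list_matching_n_is_used_as_is(self):
        spec = hetcrt.ScenarioSpec(
            scenario_id="custom",
            family_spec=hetcrt.FamilySpec("poisson"),
            fixed=hetcrt.FixedEffects(-1.0, 0.0, (0.1,), (0.0,)),
            ranef=hetcrt.RandomEffectSpec("common_intercept", sigma2=0.1),
            n_clusters=4, cluster_sizes=(5, 6, 7, 8))
        assert np.array_equal(hetcrt.assign_cluster_sizes(spec), [5, 6, 7, 8])

    def test_nonpositive_size_rejected(self):
        with pytest.raises((ValueError, ConfigurationError)):
            hetcrt.ScenarioSpec(
                scenario_id="custom",
                family_spec=hetcrt.FamilySpec("poisson"),
                fixed=hetcrt.FixedEffects(-1.0, 0.0, (0.1,), (0.0,)),
                ranef=hetcrt.RandomEffectSpec("common_intercept", sigma2=0.1),
                n_clusters=4, cluster_sizes=(5, 0, 7, 8))


def _custom_gauss_spec(Sigma, n_clusters=40, size=50, arm_scale=(1.0, 1.0)):
    return hetcrt.ScenarioSpec(
        scenario_id="custom",
        family_spec=hetcrt.FamilySpec("gaussian", residual_sd=0.8),
        fixed=hetcrt.FixedEffects(0.0, 0.5, (0.3,), (0.0,)),
        ranef=hetcrt.RandomEffectSpec("subgroup_specific", Sigma=np.asarray(Sigma),
                                      arm_scale=arm_scale),
        n_clusters=n_clusters, cluster_sizes=size)


class TestRandomEffects:
    def test_zero_covariance_gives_zero_effects(self):
        spec = _custom_gauss_spec(np.zeros((2, 2)))
        arms = hetcrt.randomize_clusters(spec.n_clusters, 0)
        u = hetcrt.draw_random_effects(spec, arms, 1)
        assert np.all(u == 0.0)

    def test_empirical_covariance_matches_sigma(self):
        Sigma = np.array([[0.2, 0.13], [0.13, 0.1]])
        spec = _custom_gauss_spec(Sigma, n_clusters=20000)
        arms = hetcrt.randomize_clusters(spec.n_clusters, 0)
        u = hetcrt.draw_random_effects(spec, arms, 3)
        emp = np.cov(u.T)
        # 2 MC standard errors: se(cov) ~ sqrt((s_ii s_jj + s_ij^2)/n)
        for i in range(2):
            for j in range(2):
                se = np.sqrt((Sigma[i, i] * Sigma[j, j] + Sigma[i, j] ** 2) / 20000)
                assert abs(emp[i, j] - Sigma[i, j]) < 2.5 * se

    def test_arm_scaling_applies_control_factor(self):
        Sigma = np.array([[0.2, 0.13], [0.13, 0.1]])
        spec = _custom_gauss_spec(Sigma, n_clusters=40000, arm_scale=(1.4, 1.0))
        arms = hetcrt.randomize_clusters(spec.n_clusters, 0)
        u = hetcrt.draw_random_effects(spec, arms, 4)
        v_control = np.cov(u[arms == 0].T)
        v_trt = np.cov(u[arms == 1].T)
        assert abs(v_control[0, 0] - 1.4 * 0.2) < 3 * np.sqrt(2 * (1.4 * 0.2) ** 2 / 20000)
        assert abs(v_trt[0, 0] - 0.2) < 3 * np.sqrt(2 * 0.2 ** 2 / 20000)

    def test_common_intercept_repeats_one_draw(self):
        spec = hetcrt.make_scenario(4, "gaussian", 50, "fixed")
        arms = hetcrt.randomize_clusters(50, 0)
        u = hetcrt.draw_random_effects(spec, arms, 5)
        assert np.all(u[:, 0] == u[:, 1])

    def test_non_psd_sigma_rejected(self):
        with pytest.raises((ValueError, ConfigurationError)):
            _custom_gauss_spec([[0.2, 0.5], [0.5, 0.1]])


class TestSimulateTrial:
    def test_bit_identical_under_same_seed(self):
        spec = hetcrt.make_scenario(1, "poisson", 50, "fixed")
        a = hetcrt.simulate_trial(spec, 11)
        b = hetcrt.simulate_trial(spec, 11)
        assert a.frame.equals(b.frame)
        assert np.array_equal(a.latent_u, b.latent_u)
        c = hetcrt.simulate_trial(spec, 12)
        assert not a.frame["y"].equals(c.frame["y"])

    def test_treatment_constant_within_cluster_and_balanced(self):
        d = hetcrt.simulate_trial(hetcrt.make_scenario(1, "gaussian", 50, "fixed"), 2)
        per_cluster = d.frame.groupby("cluster_id")["trt"].nunique()
        assert (per_cluster == 1).all()
        arms = d.frame.groupby("cluster_id")["trt"].first()
        assert arms.sum() == 25

    def test_reference_cell_means_match_links(self):
        """With the latent effects forced to zero, the reference cell mean is
        the inverse link at the intercept, and the Gaussian residual variance
        is 0.64."""
        base = dict(n_clusters=100, cluster_sizes=200)
        checks = [
            ("gaussian", 0.0, None), ("poisson", np.exp(-1.0), None),
            ("bernoulli", 1 / (1 + np.exp(1.66)), None),
        ]
        presets = {"gaussian": (0.0, 0.5, (0.3,), (0.0,)),
                   "poisson": (-1.0, -0.07, (-0.5,), (0.0,)),
                   "bernoulli": (-1.66, -0.32, (-0.08,), (0.0,))}
        for fam, target, _ in checks:
            spec = hetcrt.ScenarioSpec(
                scenario_id="custom",
                family_spec=hetcrt.FamilySpec(
                    fam, residual_sd=0.8 if fam == "gaussian" else None),
                fixed=hetcrt.FixedEffects(*presets[fam]),
                ranef=hetcrt.RandomEffectSpec(
                    "subgroup_specific", Sigma=np.zeros((2, 2))), **base)
            d = hetcrt.simulate_trial(spec, 8)
            cell = d.frame[(d.frame.trt == 0) & (d.frame.gr == 0)]
            n = len(cell)
            if fam == "gaussian":
                assert cell["y"].var() == pytest.approx(0.64, rel=0.1)
            else:
                sd = np.sqrt(max(target, 0.01) / n) * 4
                assert abs(cell["y"].mean() - target) < max(4 * cell["y"].std() / np.sqrt(n), sd)

    def test_marginal_variance_adds_residual_to_subgroup_variance(self):
        Sigma = np.array([[0.2, 0.13], [0.13, 0.1]])
        spec = _custom_gauss_spec(Sigma, n_clusters=600, size=60)
        d = hetcrt.simulate_trial(spec, 21)
        f = d.frame
        for k, truth in [(0, 0.2 + 0.64), (1, 0.1 + 0.64)]:
            sub = f[(f.trt == 0) & (f.gr == k)]["y"]
            se = truth * np.sqrt(2 / len(sub)) * 2  # crude: clustering inflates
            assert abs(sub.var() - truth) < 3 * se

    def test_latent_effects_independent_across_clusters(self):
        Sigma = np.array([[0.2, 0.13], [0.13, 0.1]])
        spec = _custom_gauss_spec(Sigma, n_clusters=4000)
        d = hetcrt.simulate_trial(spec, 22)
        u = d.latent_u
        # lag-1 cross-cluster correlation should vanish
        r = np.corrcoef(u[:-1, 0], u[1:, 0])[0, 1]
        assert abs(r) < 3 / np.sqrt(len(u))
        # within-cluster cross-subgroup covariance matches Sigma[0,1]
        cov01 = np.mean(u[:, 0] * u[:, 1])
        assert abs(cov01 - 0.13) < 3 * np.sqrt((0.2 * 0.1 + 0.13 ** 2) / 4000)

    def test_common_intercept_equals_rank_one_sigma_in_moments(self):
        n = 800
        common = hetcrt.ScenarioSpec(
            scenario_id="custom", family_spec=hetcrt.FamilySpec("gaussian", 0.8),
            fixed=hetcrt.FixedEffects(0.0, 0.5, (0.3,), (0.0,)),
            ranef=hetcrt.RandomEffectSpec("common_intercept", sigma2=0.3),
            n_clusters=n, cluster_sizes=40)
        rank1 = hetcrt.ScenarioSpec(
            scenario_id="custom", family_spec=hetcrt.FamilySpec("gaussian", 0.8),
            fixed=hetcrt.FixedEffects(0.0, 0.5, (0.3,), (0.0,)),
            ranef=hetcrt.RandomEffectSpec("subgroup_specific",
                                          Sigma=0.3 * np.ones((2, 2))),
            n_clusters=n, cluster_sizes=40)
        da = hetcrt.simulate_trial(common, 33)
        db = hetcrt.simulate_trial(rank1, 34)
        for d in (da, db):
            assert np.allclose(np.cov(d.latent_u.T), 0.3 * np.ones((2, 2)), atol=0.04)
        ya, yb = da.frame["y"], db.frame["y"]
        assert ya.mean() == pytest.approx(yb.mean(), abs=0.05)
        assert ya.var() == pytest.approx(yb.var(), rel=0.08)

    def test_csv_roundtrip(self, tmp_path):
        d = hetcrt.simulate_trial(hetcrt.make_scenario(3, "bernoulli", 12, "varying"), 3)
        path = tmp_path / "trial.csv"
        d.to_csv(path)
        assert path.read_text().splitlines()[0] == "cluster_id,trt,gr,y"
        back = hetcrt.TrialData.from_csv(path)
        assert back.frame.equals(d.frame[["cluster_id", "trt", "gr", "y"]])
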