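"""Model densities and predictor structure against brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

import cmtrends as ct
from cmtrends.model import ModelConfig, ParameterLayout, ParameterState, \
    SD_NAMES, build_model_data, log_likelihood, log_posterior, log_prior, \
    linear_predictor, age_curve, rw2_log_density
from conftest import random_state


def zero_state(layout):
    return ParameterState(layout, np.zeros(layout.n_coef),
                          np.full(layout.n_sd, 0.1))


class TestLinearPredictor:
    def test_global_intercept_only(self, small_layout):
        state = zero_state(small_layout)
        state.coef[small_layout.slices["g0"]] = 1.7
        for country, year, age in (("C01", 1995, 25), ("C04", 2005, 85)):
            assert linear_predictor(state, country, year, age) == \
                pytest.approx(1.7)

    def test_national_study_has_no_coverage_or_urban_term(self, small_layout):
        rng = np.random.default_rng(0)
        state = random_state(small_layout, rng)
        a = linear_predictor(state, "C02", 2000, 45.0, coverage="national",
                             urban_dev=0.0)
        # zero out all coverage/urbanisation effects: prediction unchanged
        for nm in ("delta_sub", "delta_comm", "delta_urb", "delta_rural",
                   "delta_urban"):
            state.coef[small_layout.slices[nm]] = 0.0
        assert linear_predictor(state, "C02", 2000, 45.0) == pytest.approx(a)

    def test_subnational_offset_is_exact_difference(self, small_layout):
        rng = np.random.default_rng(1)
        state = random_state(small_layout, rng)
        state.coef[small_layout.slices["delta_sub"]] = 0.3
        nat = linear_predictor(state, "C03", 1999, 35.0, coverage="national")
        sub = linear_predictor(state, "C03", 1999, 35.0, coverage="subnational")
        assert sub - nat == pytest.approx(0.3, abs=1e-12)

    def test_predictor_affine_in_coverage_effect(self, small_model_data):
        """Finite difference of the likelihood design wrt delta_sub is the
        subnational indicator: 1 for subnational rows, 0 otherwise."""
        data = small_model_data
        col = data.A[:, data.layout.slices["delta_sub"].start]
        assert np.array_equal(col, (data.coverage_code == 1).astype(float))

    def test_unknown_country_rejected(self, small_layout):
        with pytest.raises(ValueError, match="unknown country"):
            linear_predictor(zero_state(small_layout), "XX", 2000, 45.0)


class TestRW2Density:
    def test_linear_series_maximises_density(self):
        t = np.arange(8, dtype=float)
        linear = 0.5 + 0.2 * t
        curved = linear + 0.01 * (t - 4) ** 2
        assert rw2_log_density(linear, 0.1) > rw2_log_density(curved, 0.1)

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            u = rng.normal(0, 1, 5)
            sd = float(rng.uniform(0.1, 2.0))
            expected = sum(
                stats.norm.logpdf(u[i + 1] - 2 * u[i] + u[i - 1], 0, sd)
                for i in range(1, 4))
            assert rw2_log_density(u, sd) == pytest.approx(expected, rel=1e-12)

    def test_scaling_curvature_reduces_density(self):
        u = np.array([0.0, 0.1, 0.5, 0.2, -0.1])
        assert rw2_log_density(2 * u, 0.3) < rw2_log_density(u, 0.3)

    @pytest.mark.parametrize("u,sd", [([1.0, 2.0], 0.1), ([1, 2, 3], 0.0),
                                      ([1, 2, 3], -1.0)])
    def test_invalid_inputs(self, u, sd):
        with pytest.raises(ValueError):
            rw2_log_density(np.asarray(u, dtype=float), sd)


class TestAgeCurve:
    def test_zero_at_reference_age_for_any_state(self, small_layout):
        rng = np.random.default_rng(4)
        for _ in range(5):
            state = random_state(small_layout, rng)
            for country in small_layout.countries:
                assert age_curve(state, country, small_layout.config.ref_age) \
                    == pytest.approx(0.0, abs=1e-12)

    def test_no_deviations_means_identical_curves(self, small_layout):
        state = zero_state(small_layout)
        state.coef[small_layout.slices["age_global"]] = \
            np.random.default_rng(5).normal(0, 1, small_layout.n_age_basis)
        curves = [[age_curve(state, c, a) for a in (25, 35, 55, 75, 85)]
                  for c in small_layout.countries]
        for row in curves[1:]:
            assert row == pytest.approx(curves[0])

    def test_basis_matches_cox_de_boor_recursion(self, small_layout):
        """The spline design row equals a direct Cox-de Boor evaluation."""
        basis = small_layout.age
        t, k = basis._t, basis.degree

        def cox_de_boor(x, i, d):
            if d == 0:
                return 1.0 if t[i] <= x < t[i + 1] else 0.0
            left = 0.0
            if t[i + d] != t[i]:
                left = (x - t[i]) / (t[i + d] - t[i]) * cox_de_boor(x, i, d - 1)
            right = 0.0
            if t[i + d + 1] != t[i + 1]:
                right = (t[i + d + 1] - x) / (t[i + d + 1] - t[i + 1]) * \
                    cox_de_boor(x, i + 1, d - 1)
            return left + right

        for x in (19.0, 33.5, 45.0, 62.0, 84.5):
            row = basis._raw(np.array([x]))[0]
            brute = [cox_de_boor(x, i, k) for i in range(basis.n_basis)]
            assert row == pytest.approx(brute, abs=1e-12)

    def test_age_outside_span_rejected(self, small_layout):
        with pytest.raises(ValueError, match="outside"):
            age_curve(zero_state(small_layout), "C01", 140.0)


class TestLikelihoodAndPrior:
    def test_empty_observation_set_gives_zero(self, small_hierarchy,
                                              small_covariates, small_truth):
        obs = ct.sample_surveys(small_truth,
                                ct.SurveyDesign(studies_per_country=1), seed=0)
        empty = obs[obs.sex == "men"].iloc[:0]
        cfg = ModelConfig(outcome_kind="prev_diabetes",
                          covariates=("urbanisation",), year_center=2000.0)
        data = build_model_data(empty, small_hierarchy, small_covariates, cfg)
        state = random_state(data.layout, np.random.default_rng(0))
        assert log_likelihood(state, data) == 0.0
        assert log_posterior(state, data) == pytest.approx(log_prior(state))

    def test_single_observation_analytic_value(self, small_model_data):
        data = small_model_data
        state = zero_state(data.layout)
        # force the predictor to match the first observation exactly
        import copy
        one = copy.copy(data)
        one.A, one.y = data.A[:1], data.y[:1]
        one.sampling_var = data.sampling_var[:1]
        one.coverage_code = data.coverage_code[:1]
        state.coef[:] = 0.0
        state.coef[data.layout.slices["g0"]] = one.y[0]
        # make every other design column of that row irrelevant
        one.A = np.zeros_like(one.A)
        one.A[0, data.layout.slices["g0"].start] = 1.0
        v = one.sampling_var[0] + state.tau()[one.coverage_code[0]] ** 2
        assert log_likelihood(state, one) == \
            pytest.approx(-0.5 * np.log(2 * np.pi * v), rel=1e-12)

    def test_matches_brute_force_row_sum(self, small_model_data):
        data = small_model_data
        rng = np.random.default_rng(6)
        state = random_state(data.layout, rng)
        tau = state.tau()
        expected = 0.0
        for i in range(10):
            mu = float(data.A[i] @ state.coef)
            v = data.sampling_var[i] + tau[data.coverage_code[i]] ** 2
            expected += stats.norm.logpdf(data.y[i], mu, np.sqrt(v))
        import copy
        ten = copy.copy(data)
        ten.A, ten.y = data.A[:10], data.y[:10]
        ten.sampling_var = data.sampling_var[:10]
        ten.coverage_code = data.coverage_code[:10]
        assert log_likelihood(state, ten) == pytest.approx(expected, rel=1e-10)

    def test_permutation_invariance(self, small_model_data):
        import copy
        data = small_model_data
        state = random_state(data.layout, np.random.default_rng(7))
        perm = np.random.default_rng(8).permutation(data.n_obs)
        shuffled = copy.copy(data)
        shuffled.A = data.A[perm]
        shuffled.y = data.y[perm]
        shuffled.sampling_var = data.sampling_var[perm]
        shuffled.coverage_code = data.coverage_code[perm]
        assert log_likelihood(state, shuffled) == \
            pytest.approx(log_likelihood(state, data), rel=1e-14)

    def test_prior_matches_brute_force(self, small_layout):
        """Independent recomputation of every prior block with scipy."""
        rng = np.random.default_rng(9)
        cfg = small_layout.config
        for _ in range(5):
            state = random_state(small_layout, rng)
            exp = 0.0
            for nm in ("g0", "g1", "age_global", "cov", "delta_sub",
                       "delta_comm", "delta_urb", "delta_rural", "delta_urban"):
                exp += stats.norm.logpdf(state.block(nm), 0,
                                         cfg.prior_fixed_sd).sum()
            for nm, sd_nm in (("region_int", "sd_region_int"),
                              ("region_slope", "sd_region_slope"),
                              ("country_int", "sd_country_int"),
                              ("country_slope", "sd_country_slope"),
                              ("age_country", "sd_age_dev")):
                exp += stats.norm.logpdf(state.block(nm), 0,
                                         state.sd(sd_nm)).sum()
            for u in state.rw2_series():
                d2 = np.diff(u, n=2)
                exp += stats.norm.logpdf(d2, 0, state.sd("sd_rw2")).sum()
            exp += stats.halfnorm.logpdf(state.sds, 0,
                                         cfg.prior_sd_scale).sum()
            assert log_prior(state) == pytest.approx(exp, rel=1e-10)

    def test_negative_sd_state_rejected(self, small_layout):
        state = zero_state(small_layout)
        state.sds[2] = -0.5
        assert log_prior(state) == -np.inf

    def test_rw2_constraints_hold_by_construction(self, small_layout):
        state = random_state(small_layout, np.random.default_rng(10))
        t = np.arange(small_layout.hierarchy.n_years, dtype=float)
        for u in state.rw2_series():
            assert abs(u.sum()) < 1e-9
            assert abs((t - t.mean()) @ u) < 1e-9

    def test_non_finite_transformed_value_named(self, small_hierarchy,
                                                small_covariates, small_truth):
        obs = ct.sample_surveys(small_truth,
                                ct.SurveyDesign(studies_per_country=1), seed=0)
        men = obs[obs.sex == "men"].reset_index(drop=True)
        men.loc[0, "value"] = 0.0  # logit(0) = -inf
        cfg = ModelConfig(outcome_kind="prev_diabetes",
                          covariates=("urbanisation",), year_center=2000.0)
        with pytest.raises(ValueError, match="rows \\[0\\]"):
            build_model_data(men, small_hierarchy, small_covariates, cfg)


class TestModelConfig:
    def test_describe_mentions_all_components(self):
        text = ModelConfig(outcome_kind="prev_raised_bp").describe()
        for word in ("logit", "RW2", "B-spline", "delta_sub", "half-Normal"):
            assert word in text

    def test_default_covariates_per_outcome(self):
        from cmtrends.model import default_covariates
        assert default_covariates("mean_bmi") == ("urbanisation",)
        assert "mean_bmi" in default_covariates("prev_diabetes")
        assert "education" in default_covariates("mean_sbp")

    def test_bad_prior_scale_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ModelConfig(prior_fixed_sd=0.0)
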