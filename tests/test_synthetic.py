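"""Truth-surface generation, survey sampling and microdata laws."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cmtrends as ct
from cmtrends.bands import AgeBand
from cmtrends.outcomes import expit, logit
from cmtrends.synthetic import PersonLaw

QUIET = dict(sd_region_int=0.0, sd_region_slope=0.0, sd_country_int=0.0,
             sd_country_slope=0.0, sd_rw2=0.0, sd_age_dev=0.0,
             age_curve_scale=0.0, covariate_effects={})

NOISELESS = dict(coverage_probs=(1.0, 0.0, 0.0), p_urban_only=0.0,
                 p_rural_only=0.0, p_urban_unknown=1.0,
                 random_effect_sd={"national": 0.0, "subnational": 0.0,
                                   "community": 0.0},
                 sampling_noise_scale=0.0)


class TestGenerateTruth:
    def test_degenerate_truth_is_flat(self, small_hierarchy):
        settings = ct.GenerativeSettings(intercept=float(logit(0.1)),
                                         slope=0.0, **QUIET)
        truth = ct.generate_truth(small_hierarchy, settings, "prev_diabetes",
                                  seed=0)
        assert np.allclose(truth.values.values, 0.1, atol=1e-12)

    def test_zero_rw2_truth_linear_in_year(self, small_hierarchy):
        settings = ct.GenerativeSettings(slope=0.03, **QUIET)
        truth = ct.generate_truth(small_hierarchy, settings, "prev_diabetes",
                                  seed=0)
        eta = logit(truth.values.sel(sex="men", country="C02").values)  # (T, A)
        slopes = np.diff(eta, axis=0)
        assert np.allclose(slopes, 0.03, atol=1e-9)

    def test_no_missing_cells_and_prevalence_in_unit_interval(self, small_truth):
        vals = small_truth.values.values
        assert vals.shape == (2, 4, 11, 8)
        assert np.all(np.isfinite(vals))
        assert np.all((vals > 0) & (vals < 1))

    def test_same_seed_identical(self, small_hierarchy, small_covariates):
        t1 = ct.generate_truth(small_hierarchy, seed=9,
                               covariates=small_covariates)
        t2 = ct.generate_truth(small_hierarchy, seed=9,
                               covariates=small_covariates)
        assert np.array_equal(t1.values.values, t2.values.values)

    def test_negative_variance_component_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            ct.GenerativeSettings(sd_rw2=-0.1)

    def test_region_effect_recovered_across_regenerations(self, small_hierarchy):
        """Monte-Carlo oracle: the region-average transformed truth at the
        central year and reference age equals the global intercept on
        average over regenerations, with spread given by the configured
        region/country SDs."""
        g0, sd_r, sd_c = float(logit(0.1)), 0.3, 0.2
        settings = ct.GenerativeSettings(
            intercept=g0, slope=0.0, sd_region_int=sd_r, sd_country_int=sd_c,
            sd_region_slope=0.0, sd_country_slope=0.0, sd_rw2=0.0,
            sd_age_dev=0.0, age_curve_scale=0.0, covariate_effects={})
        n_rep = 200
        devs = np.empty(n_rep)
        h = small_hierarchy
        for s in range(n_rep):
            truth = ct.generate_truth(h, settings, "prev_diabetes", seed=1000 + s)
            # band 40-50 has midpoint 45 = reference age; year 2000 is central
            cell = truth.values.sel(sex="men", year=2000, age_group="40-50")
            region_avg = float(logit(cell.sel(country=["C01", "C02"]).values).mean())
            devs[s] = region_avg - g0
        spread = np.sqrt(sd_r ** 2 + sd_c ** 2 / 2)  # 2 countries per region
        assert abs(devs.mean()) < 3 * spread / np.sqrt(n_rep)
        assert np.isclose(devs.std(), spread, rtol=0.25)


class TestSampleSurveys:
    def test_zero_noise_observations_equal_truth(self, small_truth):
        design = ct.SurveyDesign(studies_per_country=3, **NOISELESS)
        obs = ct.sample_surveys(small_truth, design, seed=2)
        for row in obs.itertuples(index=False):
            band = f"{int(row.age_lo)}-{int(row.age_hi)}" \
                if np.isfinite(row.age_hi) else f"{int(row.age_lo)}+"
            tv = float(small_truth.values.sel(sex=row.sex, country=row.country,
                                              year=row.year, age_group=band))
            assert row.value == pytest.approx(tv, abs=1e-12)

    def test_forced_subnational_offset(self, small_truth):
        kwargs = dict(NOISELESS)
        kwargs["coverage_probs"] = (0.0, 1.0, 0.0)
        design = ct.SurveyDesign(studies_per_country=3, delta_sub=0.3, **kwargs)
        obs = ct.sample_surveys(small_truth, design, seed=2)
        assert (obs["coverage"] == "subnational").all()
        for row in obs.head(40).itertuples(index=False):
            band = f"{int(row.age_lo)}-{int(row.age_hi)}" \
                if np.isfinite(row.age_hi) else f"{int(row.age_lo)}+"
            tv = float(small_truth.values.sel(sex=row.sex, country=row.country,
                                              year=row.year, age_group=band))
            assert logit(row.value) - logit(tv) == pytest.approx(0.3, abs=1e-9)

    def test_replicate_average_recovers_truth(self, small_hierarchy):
        """1000 replicate national studies of one cell average to the truth
        value within 3 Monte-Carlo standard errors."""
        settings = ct.GenerativeSettings(intercept=float(logit(0.1)),
                                         slope=0.0, **QUIET)
        truth = ct.generate_truth(small_hierarchy, settings, "prev_diabetes",
                                  seed=0)
        design = ct.SurveyDesign(
            studies_per_country={"C01": 1000}, coverage_probs=(1.0, 0.0, 0.0),
            p_urban_only=0.0, p_rural_only=0.0, p_urban_unknown=1.0,
            random_effect_sd={"national": 0.05, "subnational": 0.0,
                              "community": 0.0},
            sample_size_median=2000, sample_size_sigma=0.0,
            years=(2000, 2000))
        obs = ct.sample_surveys(truth, design, seed=5)
        cell = obs[(obs.sex == "men") & (obs.age_lo == 40)]
        assert len(cell) == 1000
        p = 0.1
        total_sd = np.sqrt(p * p * (1 - p) * (1 - p)
                           * (1 / (2000 * p * (1 - p)) + 0.05 ** 2))
        mc_se = total_sd / np.sqrt(len(cell))
        assert abs(cell["value"].mean() - p) < 3 * mc_se

    def test_random_effect_sd_matches_configuration(self, small_hierarchy):
        """Across many studies the empirical SD of the study random effect
        matches the configured value within 10%."""
        settings = ct.GenerativeSettings(intercept=float(logit(0.2)),
                                         slope=0.0, **QUIET)
        truth = ct.generate_truth(small_hierarchy, settings, "prev_diabetes",
                                  seed=0)
        tau = 0.2
        design = ct.SurveyDesign(
            studies_per_country=200, coverage_probs=(1.0, 0.0, 0.0),
            p_urban_only=0.0, p_rural_only=0.0, p_urban_unknown=1.0,
            random_effect_sd={"national": tau, "subnational": 0.0,
                              "community": 0.0},
            sampling_noise_scale=0.0)
        obs = ct.sample_surveys(truth, design, seed=6)
        effects = logit(obs["value"].to_numpy()) - float(logit(0.2))
        assert len(effects) >= 500
        assert np.isclose(effects.std(), tau, rtol=0.10)

    def test_design_years_outside_truth_rejected(self, small_truth):
        design = ct.SurveyDesign(years=(1980, 2005))
        with pytest.raises(ValueError, match="outside the truth grid"):
            ct.sample_surveys(small_truth, design, seed=0)

    def test_same_seed_identical_tables(self, small_truth):
        a = ct.sample_surveys(small_truth, ct.SurveyDesign(studies_per_country=2),
                              seed=4)
        b = ct.sample_surveys(small_truth, ct.SurveyDesign(studies_per_country=2),
                              seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ct.SurveyDesign(coverage_probs=(0.5, 0.2, 0.2))
        with pytest.raises(ValueError, match=">= 25"):
            ct.SurveyDesign(min_sample_size=10)


class TestMicrodata:
    def test_degenerate_bmi_law(self):
        law = PersonLaw(bmi_median=31.0, bmi_sigma=0.0)
        recs = ct.generate_microdata(law, 50, "prev_obesity", seed=1)
        assert all(r.bmi == pytest.approx(31.0) for r in recs)
        assert all(ct.obesity_case(r) for r in recs)

    def test_raised_bp_tail_probability(self):
        """SBP ~ N(130, 10), DBP degenerate at 80: prevalence converges to
        1 - Phi(1) ~ 0.1587."""
        law = PersonLaw(sbp_mean=130.0, sbp_sd=10.0, dbp_mean=80.0, dbp_sd=0.0)
        n = 50_000
        recs = ct.generate_microdata(law, n, "prev_raised_bp", seed=2)
        p_hat = np.mean([ct.raised_bp_case(r) for r in recs])
        p = 1 - stats.norm.cdf(1.0)
        assert abs(p_hat - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_diabetes_composite_probability(self):
        """FPG lognormal tail plus independent treatment flag."""
        law = PersonLaw(fpg_median=5.5, fpg_sigma=0.15, p_treatment=0.1)
        n = 50_000
        recs = ct.generate_microdata(law, n, "prev_diabetes", seed=3)
        p_hat = np.mean([ct.diabetes_case(r) for r in recs])
        p_fpg = 1 - stats.norm.cdf(np.log(7.0 / 5.5) / 0.15)
        p = 1 - (1 - p_fpg) * (1 - 0.1)
        assert abs(p_hat - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_same_seed_identical_records(self):
        law = PersonLaw(bmi_median=27.0)
        a = ct.generate_microdata(law, 20, "prev_obesity", seed=9,
                                  age_band=AgeBand(20, 30))
        b = ct.generate_microdata(law, 20, "prev_obesity", seed=9,
                                  age_band=AgeBand(20, 30))
        assert a == b

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError, match=">= 1"):
            ct.generate_microdata(PersonLaw(bmi_median=25.0), 0, "prev_obesity")
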