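"""Case definitions, coverage classes, study summaries and table I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import cmtrends as ct
from cmtrends.bands import AgeBand
from cmtrends.ingest import COMMUNITY, NATIONAL, SUBNATIONAL, SURVEY_COLUMNS, \
    clamp_proportion
from cmtrends.synthetic import PersonLaw


class TestClassifyCoverage:
    @pytest.mark.parametrize("args,expected", [
        ((False, 2, 0), SUBNATIONAL),    # covers >= 1 subnational region
        ((False, 1, 0), SUBNATIONAL),
        ((False, 0, 4), SUBNATIONAL),    # > 3 communities
        ((False, 0, 3), COMMUNITY),      # <= 3 communities
        ((False, 0, 1), COMMUNITY),
        ((True, 0, 0), NATIONAL),        # flag wins
        ((True, 2, 5), NATIONAL),
    ])
    def test_classification(self, args, expected):
        assert ct.classify_coverage(*args) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            ct.classify_coverage(False, -1, 2)

    def test_non_national_with_no_coverage_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            ct.classify_coverage(False, 0, 0)


class TestCaseDefinitions:
    @pytest.mark.parametrize("bmi,expected", [
        (29.9, False), (30.0, True), (35.2, True), (None, None)])
    def test_obesity_threshold_inclusive(self, bmi, expected):
        rec = ct.PersonRecord(bmi=bmi, sbp=120.0)
        assert ct.obesity_case(rec) is expected

    @pytest.mark.parametrize("sbp,dbp,expected", [
        (150.0, 80.0, True),    # systolic criterion alone
        (130.0, 95.0, True),    # diastolic criterion alone
        (140.0, 90.0, True),
        (139.0, 89.0, False),   # both just below threshold
        (150.0, None, None),    # single pressure is not evaluable
        (None, 95.0, None),
    ])
    def test_raised_bp(self, sbp, dbp, expected):
        rec = ct.PersonRecord(sbp=sbp, dbp=dbp, bmi=25.0)
        assert ct.raised_bp_case(rec) is expected

    @pytest.mark.parametrize("fpg,hist,treat,expected", [
        (7.2, False, False, True),   # biomarker criterion
        (7.0, False, False, True),
        (6.0, False, True, True),    # treatment overrides biomarker
        (6.0, True, False, True),
        (6.9, False, False, False),
        (None, None, None, None),    # nothing to evaluate
    ])
    def test_diabetes(self, fpg, hist, treat, expected):
        kwargs = dict(fpg=fpg, diabetes_history=hist, diabetes_treatment=treat)
        if all(v is None for v in kwargs.values()):
            kwargs["bmi"] = 25.0
        assert ct.diabetes_case(ct.PersonRecord(**kwargs)) is expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(bmi=st.floats(10, 60), sbp=st.floats(80, 220), dbp=st.floats(40, 140))
    def test_flags_ignore_irrelevant_fields(self, bmi, sbp, dbp):
        """Changing blood pressure never changes the obesity flag, etc."""
        a = ct.PersonRecord(bmi=bmi, sbp=sbp, dbp=dbp, fpg=5.0)
        b = ct.PersonRecord(bmi=bmi, sbp=200.0, dbp=130.0, fpg=9.0)
        assert ct.obesity_case(a) == ct.obesity_case(b)
        c = ct.PersonRecord(bmi=45.0, sbp=sbp, dbp=dbp)
        assert ct.raised_bp_case(a) == ct.raised_bp_case(c)

    def test_record_without_outcomes_rejected(self):
        with pytest.raises(ValueError, match="no outcome"):
            ct.PersonRecord(age=40.0)


class TestSummariseStudy:
    BAND = (AgeBand(20, 80),)

    def test_prevalence_is_case_fraction(self):
        recs = [ct.PersonRecord(age=30, bmi=b) for b in (28.0, 31.0, 35.0)]
        out = ct.summarise_study(recs, "prev_obesity", self.BAND)
        assert out == [{"age_band": self.BAND[0], "value": pytest.approx(2 / 3),
                        "n": 3}]

    def test_empty_band_omitted(self):
        recs = [ct.PersonRecord(age=30, bmi=25.0)]
        out = ct.summarise_study(recs, "prev_obesity",
                                 (AgeBand(20, 40), AgeBand(40, 60)))
        assert [o["age_band"] for o in out] == [AgeBand(20, 40)]

    def test_mean_outcome(self):
        recs = [ct.PersonRecord(age=50, sbp=s, dbp=80.0)
                for s in (120.0, 130.0, 140.0)]
        out = ct.summarise_study(recs, "mean_sbp", self.BAND)
        assert out[0]["value"] == pytest.approx(130.0)

    def test_large_sample_matches_closed_form(self):
        """Raised-BP prevalence from simulated microdata converges to the
        normal-tail probability 1 - Phi((140-130)/10) = 1 - Phi(1)."""
        law = PersonLaw(sbp_mean=130.0, sbp_sd=10.0, dbp_mean=80.0, dbp_sd=0.0)
        n = 40_000
        recs = ct.generate_microdata(law, n, "prev_raised_bp", seed=4,
                                     age_band=AgeBand(20, 80))
        out = ct.summarise_study(recs, "prev_raised_bp", self.BAND)
        p = 1 - stats.norm.cdf(1.0)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(out[0]["value"] - p) < 3 * se


class TestObservationVariance:
    @pytest.mark.parametrize("p,n,expected", [
        (0.5, 100, 0.04),    # 1 / (100 * 0.25)
        (0.5, 400, 0.01),    # 1 / (400 * 0.25)
    ])
    def test_delta_method_formula(self, p, n, expected):
        assert ct.observation_variance(p, n, "prev_obesity") == \
            pytest.approx(expected, rel=1e-12)

    def test_degenerate_proportion_clamped(self):
        v = ct.observation_variance(0.0, 10, "prev_diabetes")
        assert np.isfinite(v)
        p_tilde = clamp_proportion(0.0, 10)
        assert p_tilde == 0.05
        assert v == pytest.approx(1 / (10 * 0.05 * 0.95), rel=1e-12)

    def test_mean_outcome_variance(self):
        from cmtrends.outcomes import MEAN_OUTCOME_SD
        v = ct.observation_variance(26.0, 50, "mean_bmi")
        assert v == pytest.approx(MEAN_OUTCOME_SD["mean_bmi"] ** 2 / 50)

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ct.observation_variance(0.3, 0, "prev_obesity")

    def test_matches_brute_force_from_records(self):
        """summarise_study + observation_variance equal a direct
        computation from the raw person records."""
        rng = np.random.default_rng(0)
        recs = [ct.PersonRecord(age=35.0, bmi=float(b))
                for b in rng.normal(28, 4, 60)]
        out = ct.summarise_study(recs, "prev_obesity", (AgeBand(20, 80),))[0]
        flags = [r.bmi >= 30 for r in recs]
        p_hat = sum(flags) / len(flags)
        assert out["value"] == pytest.approx(p_hat)
        v = ct.observation_variance(out["value"], out["n"], "prev_obesity")
        p_t = min(max(p_hat, 0.5 / 60), 1 - 0.5 / 60)
        assert v == pytest.approx(1 / (60 * p_t * (1 - p_t)), rel=1e-12)


class TestTableIO:
    def test_round_trip(self, tmp_path, small_truth):
        table = ct.sample_surveys(small_truth,
                                  ct.SurveyDesign(studies_per_country=2), seed=1)
        path = tmp_path / "surveys.csv"
        ct.write_survey_table(table, path)
        back = ct.read_survey_table(path, years=(1995, 2005))
        pd.testing.assert_frame_equal(back, table.reset_index(drop=True),
                                      check_dtype=False)

    def test_lenient_mode_drops_bad_rows(self, tmp_path, small_truth):
        table = ct.sample_surveys(small_truth,
                                  ct.SurveyDesign(studies_per_country=2), seed=1)
        table.loc[0, "year"] = 1950
        path = tmp_path / "surveys.csv"
        ct.write_survey_table(table, path)
        with pytest.raises(ValueError, match="year outside"):
            ct.read_survey_table(path, years=(1995, 2005), strict=True)
        with pytest.warns(UserWarning, match="dropping 1"):
            back = ct.read_survey_table(path, years=(1995, 2005), strict=False)
        assert len(back) == len(table) - 1

    def test_malformed_header_names_missing_columns(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"study_id": [], "country": []}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="value"):
            ct.read_survey_table(path)

    def test_unknown_country_flagged(self, tmp_path, small_truth,
                                     small_hierarchy):
        table = ct.sample_surveys(small_truth,
                                  ct.SurveyDesign(studies_per_country=1), seed=1)
        table.loc[0, "country"] = "ZZ"
        path = tmp_path / "surveys.csv"
        ct.write_survey_table(table, path)
        with pytest.raises(ValueError, match="unknown country"):
            ct.read_survey_table(path, years=(1995, 2005),
                                 hierarchy=small_hierarchy)

    def test_hierarchy_round_trip(self, tmp_path, small_hierarchy):
        h = small_hierarchy
        pd.DataFrame({"country": h.countries,
                      "region": [h.region_of[c] for c in h.countries]}
                     ).to_csv(tmp_path / "h.csv", index=False)
        h.population.to_csv(tmp_path / "p.csv", index=False)
        h.urban_fraction.to_csv(tmp_path / "u.csv", index=False)
        back = ct.read_hierarchy(tmp_path / "h.csv", tmp_path / "p.csv",
                                 tmp_path / "u.csv")
        assert back.countries == h.countries
        assert back.region_of == h.region_of
        assert back.age_bands == h.age_bands
        assert np.array_equal(back.years, h.years)
        assert back.adult_population("C03", 2000) == \
            pytest.approx(h.adult_population("C03", 2000))
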