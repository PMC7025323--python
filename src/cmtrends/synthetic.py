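"""Synthetic ground truth and survey observations with known structure.

The generator draws a true risk-factor surface from exactly the structure
the model assumes — additive global/region/country intercepts and slopes,
a doubly-constrained RW2 deviation per country, country-varying age
curves on a pinned B-spline basis, and standardised country-year
covariate effects, all on the transformed scale (logit for prevalences) —
then simulates study observations around it with coverage-class offsets,
urbanisation effects, study-level random effects and sample-size-driven
sampling noise.  Because the truth is expressed as a
:class:`~cmtrends.model.ParameterState`, recovery experiments can compare
posterior draws to generating values block by block, and a degenerate
posterior built from the truth reproduces the surface exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

from .bands import AgeBand
from .hierarchy import RegionHierarchy, make_hierarchy
from .ingest import COMMUNITY, NATIONAL, SUBNATIONAL, SEXES, SURVEY_COLUMNS, \
    observation_variance
from .model import CovariateStandardizer, ModelConfig, ParameterLayout, \
    ParameterState
from .outcomes import MIN_AGE, from_transformed, is_prevalence, \
    to_transformed, validate_outcome

_SD_FIELDS = ("sd_region_int", "sd_region_slope", "sd_country_int",
              "sd_country_slope", "sd_rw2", "sd_age_dev")


@dataclass(frozen=True)
class GenerativeSettings:
    """Transformed-scale parameters of the true surface.

    Defaults describe a diabetes-like prevalence: mid-period level around
    8%, odds roughly doubling over 1980-2014, a strongly increasing age
    gradient, and moderate between-region / between-country spread.
    """

    intercept: float = -2.4423  # logit(0.08)
    slope: float = 0.022        # per year, transformed scale
    sd_region_int: float = 0.35
    sd_region_slope: float = 0.004
    sd_country_int: float = 0.30
    sd_country_slope: float = 0.005
    sd_rw2: float = 0.012
    sd_age_dev: float = 0.15
    age_curve_scale: float = 1.3
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"urbanisation": 0.3})

    def __post_init__(self) -> None:
        for name in _SD_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"variance component {name} must be nonnegative")


@dataclass(frozen=True)
class SurveyDesign:
    """Study-sampling law around a truth surface."""

    studies_per_country: int | Mapping[str, int] = 10
    coverage_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)
    p_urban_only: float = 0.08
    p_rural_only: float = 0.05
    p_urban_unknown: float = 0.10
    delta_sub: float = 0.2
    delta_comm: float = 0.35
    delta_urb: float = 0.25
    delta_rural_only: float = 0.0
    delta_urban_only: float = 0.0
    random_effect_sd: Mapping[str, float] = field(
        default_factory=lambda: {NATIONAL: 0.05, SUBNATIONAL: 0.10,
                                 COMMUNITY: 0.15})
    sample_size_median: float = 600.0
    sample_size_sigma: float = 0.8
    min_sample_size: int = 25
    sampling_noise_scale: float = 1.0
    band_report_prob: float = 1.0
    years: tuple[int, int] | None = None   # restrict study years (default: all)

    def __post_init__(self) -> None:
        probs = np.asarray(self.coverage_probs, float)
        if np.any(probs < 0) or np.any(probs > 1) or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("coverage-class probabilities must be in [0,1] "
                             "and sum to 1")
        for p in (self.p_urban_only, self.p_rural_only, self.p_urban_unknown,
                  self.band_report_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.min_sample_size < 25:
            raise ValueError("minimum sample size must be >= 25")
        if any(v < 0 for v in self.random_effect_sd.values()):
            raise ValueError("random-effect SDs must be nonnegative")

    def n_studies(self, country: str) -> int:
        if isinstance(self.studies_per_country, Mapping):
            return int(self.studies_per_country.get(country, 0))
        return int(self.studies_per_country)


@dataclass
class TruthSurface:
    """True outcome surface plus the parameters that generated it."""

    outcome_kind: str
    hierarchy: RegionHierarchy
    values: xr.DataArray            # (sex, country, year, age) natural scale
    states: dict[str, ParameterState]
    config: ModelConfig
    standardizer: CovariateStandardizer
    bands: tuple[AgeBand, ...]
    seed: int

    def transformed(self, sex: str) -> xr.DataArray:
        return xr.apply_ufunc(lambda v: to_transformed(v, self.outcome_kind),
                              self.values.sel(sex=sex))

    def to_frame(self) -> pd.DataFrame:
        df = self.values.to_dataframe(name="value").reset_index()
        return df[["country", "year", "sex", "age_group", "value"]]


def generate_truth(hierarchy: RegionHierarchy,
                   settings: GenerativeSettings = GenerativeSettings(),
                   outcome_kind: str = "prev_diabetes",
                   seed: int = 0,
                   covariates: pd.DataFrame | None = None) -> TruthSurface:
    """Draw a :class:`TruthSurface` from the model's generative structure.

    One independent parameter set is drawn per sex.  The age curve's
    global coefficients are fitted (deterministically) so the global age
    effect approximates ``age_curve_scale * tanh((age - ref)/20)``; country
    deviations are drawn around them.
    """
    validate_outcome(outcome_kind)
    cov_names = tuple(settings.covariate_effects)
    config = ModelConfig(outcome_kind=outcome_kind, covariates=cov_names,
                         year_center=float(np.mean(hierarchy.years)))
    layout = ParameterLayout(hierarchy, config)
    std = CovariateStandardizer.fit(covariates, cov_names)

    # deterministic global age-curve coefficients: least-squares fit of the
    # pinned basis to a saturating increase with age
    ages = np.linspace(layout.age.age_range[0] + 1, layout.age.age_range[1] - 1, 80)
    target = settings.age_curve_scale * (
        np.tanh((ages - config.ref_age) / 20.0)
        - np.tanh(0.0))
    B = layout.age.design(ages)
    age_global, *_ = np.linalg.lstsq(B, target, rcond=None)

    C, Tn = layout.n_countries, hierarchy.n_years
    W, K = layout.n_rw2, layout.n_age_basis
    states: dict[str, ParameterState] = {}
    grids: dict[str, np.ndarray] = {}
    A_grid, coords = layout.grid_design(std)
    for s_i, sex in enumerate(SEXES):
        rng = np.random.default_rng(np.random.SeedSequence((seed, s_i)))
        coef = np.zeros(layout.n_coef)
        sl = layout.slices
        coef[sl["g0"]] = settings.intercept
        coef[sl["g1"]] = settings.slope
        coef[sl["region_int"]] = rng.normal(0, 1, layout.n_regions) * settings.sd_region_int
        coef[sl["region_slope"]] = rng.normal(0, 1, layout.n_regions) * settings.sd_region_slope
        coef[sl["country_int"]] = rng.normal(0, 1, C) * settings.sd_country_int
        coef[sl["country_slope"]] = rng.normal(0, 1, C) * settings.sd_country_slope
        # RW2: draw iid second differences, integrate twice, project onto the
        # doubly-constrained space (projection leaves second differences intact)
        w = np.zeros((C, W))
        for c in range(C):
            d2 = rng.normal(0, 1, Tn - 2) * settings.sd_rw2
            u_raw = np.concatenate([[0.0, 0.0], d2]).cumsum().cumsum()
            w[c] = layout.rw2.project(u_raw)
        coef[sl["rw2"]] = w.ravel()
        coef[sl["age_global"]] = age_global
        coef[sl["age_country"]] = (rng.normal(0, 1, C * K)
                                   * settings.sd_age_dev)
        coef[sl["cov"]] = [settings.covariate_effects[n] for n in cov_names]
        sds = np.array([getattr(settings, n) for n in _SD_FIELDS]
                       + [0.0, 0.0, 0.0])
        sds = np.maximum(sds, 1e-12)
        states[sex] = ParameterState(layout, coef, sds)
        grids[sex] = A_grid @ coef

    min_age = MIN_AGE[outcome_kind]
    bands = tuple(b for b in hierarchy.age_bands if b.lo >= min_age)
    nat = np.stack([
        np.asarray(from_transformed(grids[sex], outcome_kind)).reshape(
            C, Tn, len(bands))
        for sex in SEXES])
    if not np.all(np.isfinite(nat)) or (not is_prevalence(outcome_kind)
                                        and np.any(nat <= 0)):
        raise ValueError("generated truth is not finite and positive; "
                         "check the generative settings")
    values = xr.DataArray(
        nat, dims=("sex", "country", "year", "age_group"),
        coords={"sex": list(SEXES), "country": list(layout.countries),
                "year": hierarchy.years, "age_group": [b.label for b in bands]})
    return TruthSurface(outcome_kind, hierarchy, values, states, config,
                        std, bands, seed)


def sample_surveys(truth: TruthSurface, design: SurveyDesign = SurveyDesign(),
                   seed: int = 0) -> pd.DataFrame:
    """Simulate a study-level survey table around a truth surface.

    Each study draws a year, coverage class, urban composition and sample
    size, then reports one row per sex and age band: transformed truth
    + coverage offset + urbanisation term + a study-level random effect
    (drawn independently per reported row, matching the model's
    independence assumption) + sampling noise scaled by the delta-method
    variance at the true value.
    """
    h = truth.hierarchy
    rng = np.random.default_rng(np.random.SeedSequence((seed, 97)))
    if design.years is not None:
        y0, y1 = design.years
        if y0 < h.years[0] or y1 > h.years[-1]:
            raise ValueError(f"design years {design.years} outside the truth "
                             f"grid {h.years[0]}-{h.years[-1]}")
        year_pool = np.arange(y0, y1 + 1)
    else:
        year_pool = h.years
    eta = {sex: truth.transformed(sex).values for sex in SEXES}  # (C, T, A)
    band_idx = {b.label: j for j, b in enumerate(truth.bands)}
    classes = (NATIONAL, SUBNATIONAL, COMMUNITY)
    offsets = {NATIONAL: 0.0, SUBNATIONAL: design.delta_sub,
               COMMUNITY: design.delta_comm}
    rows = []
    sid = 0
    for ci, country in enumerate(h.countries):
        for _ in range(design.n_studies(country)):
            sid += 1
            study_id = f"S{sid:04d}"
            year = int(rng.choice(year_pool))
            coverage = classes[rng.choice(3, p=design.coverage_probs)]
            u = rng.random()
            urban_only = rural_only = False
            if u < design.p_urban_only:
                urban_only, uf = True, 1.0
            elif u < design.p_urban_only + design.p_rural_only:
                rural_only, uf = True, 0.0
            else:
                uf = float(rng.beta(2.0, 2.0))
            unknown_uf = (not urban_only and not rural_only
                          and rng.random() < design.p_urban_unknown)
            country_uf = h.country_urban_fraction(country, year)
            urb_dev = 0.0 if unknown_uf else uf - country_uf
            n = max(design.min_sample_size,
                    int(rng.lognormal(np.log(design.sample_size_median),
                                      design.sample_size_sigma)))
            shift = (offsets[coverage] + design.delta_urb * urb_dev
                     + design.delta_rural_only * rural_only
                     + design.delta_urban_only * urban_only)
            re_sd = design.random_effect_sd[coverage]
            t_idx = int(h.year_index(year))
            for sex in SEXES:
                for band in truth.bands:
                    if rng.random() > design.band_report_prob:
                        continue
                    mu = eta[sex][ci, t_idx, band_idx[band.label]] + shift
                    mu += rng.normal(0, 1) * re_sd
                    true_nat = from_transformed(mu, truth.outcome_kind)
                    svar = float(observation_variance(true_nat, n,
                                                      truth.outcome_kind))
                    obs_t = mu + rng.normal(0, 1) * np.sqrt(svar) \
                        * design.sampling_noise_scale
                    value = float(from_transformed(obs_t, truth.outcome_kind))
                    rows.append((study_id, country, year, sex, band.lo,
                                 band.hi if band.hi is not None else np.nan,
                                 truth.outcome_kind, value, n, coverage,
                                 np.nan if unknown_uf else uf,
                                 urban_only, rural_only))
    return pd.DataFrame(rows, columns=list(SURVEY_COLUMNS))


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def generate_covariates(hierarchy: RegionHierarchy,
                        names: tuple[str, ...] = ("urbanisation",),
                        seed: int = 0) -> pd.DataFrame:
    """Smooth country-year covariate series (long format).

    ``urbanisation`` reuses the hierarchy's urban-fraction path; other
    names get independent smooth trajectories (linear trend plus a slow
    sinusoid) per country.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
    yc = hierarchy.years - hierarchy.years.mean()
    rows = []
    for country in hierarchy.countries:
        for name in names:
            if name == "urbanisation":
                series = np.array([hierarchy.country_urban_fraction(country, y)
                                   for y in hierarchy.years])
            else:
                level = rng.normal(0.0, 1.0)
                trend = rng.normal(0.02, 0.01)
                amp = rng.normal(0.0, 0.2)
                phase = rng.uniform(0, 2 * np.pi)
                series = level + trend * yc + amp * np.sin(
                    2 * np.pi * yc / 60.0 + phase)
            rows.extend((country, int(y), name, float(v))
                        for y, v in zip(hierarchy.years, series))
    return pd.DataFrame(rows, columns=["country", "year", "covariate", "value"])


# ---------------------------------------------------------------------------
# person-level microdata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PersonLaw:
    """Person-level generating law for one population cell.

    BMI and FPG are log-normal (median and log-scale sigma), SBP and DBP
    normal, diabetes history/treatment Bernoulli.  Setting a sigma/SD to 0
    makes the measurement degenerate at its location, which gives exact
    closed-form threshold probabilities for testing.
    """

    bmi_median: float | None = None
    bmi_sigma: float = 0.16
    sbp_mean: float | None = None
    sbp_sd: float = 18.0
    dbp_mean: float | None = None
    dbp_sd: float = 11.0
    fpg_median: float | None = None
    fpg_sigma: float = 0.18
    p_history: float = 0.0
    p_treatment: float = 0.0


def generate_microdata(law: PersonLaw, n: int, outcome_kind: str, seed: int = 0,
                       age_band: AgeBand | None = None) -> list:
    """Draw person-level records for one cell from the stated laws."""
    from .ingest import PersonRecord

    validate_outcome(outcome_kind)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))
    if age_band is not None:
        hi = age_band.hi if age_band.hi is not None else age_band.lo + 10
        ages = rng.uniform(age_band.lo, hi, n)
    else:
        ages = np.full(n, np.nan)
    records = []
    for i in range(n):
        kw: dict = {"age": None if np.isnan(ages[i]) else float(ages[i])}
        if law.bmi_median is not None:
            kw["bmi"] = float(law.bmi_median *
                              np.exp(rng.normal(0, 1) * law.bmi_sigma))
        if law.sbp_mean is not None:
            kw["sbp"] = float(law.sbp_mean + rng.normal(0, 1) * law.sbp_sd)
        if law.dbp_mean is not None:
            kw["dbp"] = float(law.dbp_mean + rng.normal(0, 1) * law.dbp_sd)
        if law.fpg_median is not None:
            kw["fpg"] = float(law.fpg_median *
                              np.exp(rng.normal(0, 1) * law.fpg_sigma))
        if law.p_history > 0 or law.p_treatment > 0 or law.fpg_median is not None:
            kw["diabetes_history"] = bool(rng.random() < law.p_history)
            kw["diabetes_treatment"] = bool(rng.random() < law.p_treatment)
        records.append(PersonRecord(**kw))
    return records


# ---------------------------------------------------------------------------
# default validation scenario
# ---------------------------------------------------------------------------

HOLDOUT_COUNTRY = "C12"


def default_recovery_scenario(seed: int = 0):
    """Hierarchy, settings and design for the default recovery experiment.

    12 countries in 3 regions over 1980-2014, 10 studies per country with
    one designated hold-out country (:data:`HOLDOUT_COUNTRY`) receiving no
    studies at all, so the same run exercises both parameter recovery and
    hierarchical shrinkage for a data-free country.
    """
    hierarchy = make_hierarchy(3, [4, 4, 4], years=(1980, 2014), seed=seed)
    settings = GenerativeSettings()
    counts = {c: 10 for c in hierarchy.countries}
    counts[HOLDOUT_COUNTRY] = 0
    design = SurveyDesign(studies_per_country=counts)
    return hierarchy, settings, design
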