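"""The hierarchical Bayesian trend model.

Transformed-scale linear predictor for a study observation in country c,
year t, age a::

    eta = (g0 + r_int[R(c)] + c_int[c])
        + (g1 + r_slope[R(c)] + c_slope[c]) * (t - t_center)
        + u_c(t)                     # constrained RW2 deviation
        + f_c(a)                     # country age curve, 0 at the reference age
        + x(c, t)' beta              # standardised country-year covariates
        + delta_sub 1{subnational} + delta_comm 1{community}
        + delta_urb * (study urban fraction - country urban fraction)
        + delta_rural 1{rural-only} + delta_urban 1{urban-only}

The observed transformed value is Normal(eta, sampling variance +
tau_class^2) where tau_class is the study random-effect SD of the study's
coverage class — this marginalises the per-study random effect, so small
and non-national studies carry less weight.  Hierarchical deviations get
zero-mean normal priors with estimated SDs; all SDs get half-normal
priors; fixed effects get diffuse normal priors.  The RW2 deviation is
doubly constrained (sum zero, no linear trend) and parameterised through
:class:`~cmtrends.basis.RW2Basis`, so states satisfy the constraints by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .basis import AgeBasis, RW2Basis
from .hierarchy import RegionHierarchy
from .ingest import COMMUNITY, COVERAGE_CLASSES, NATIONAL, SUBNATIONAL, \
    observation_variance
from .outcomes import MEAN_BMI, MEAN_SBP, MIN_AGE, PREV_DIABETES, \
    PREV_OBESITY, PREV_RAISED_BP, to_transformed, validate_outcome

SD_NAMES = ("sd_region_int", "sd_region_slope", "sd_country_int",
            "sd_country_slope", "sd_rw2", "sd_age_dev",
            "tau_national", "tau_subnational", "tau_community")

_COVERAGE_CODE = {NATIONAL: 0, SUBNATIONAL: 1, COMMUNITY: 2}


def default_covariates(outcome_kind: str) -> tuple[str, ...]:
    """Per-outcome country-level covariate lists."""
    validate_outcome(outcome_kind)
    if outcome_kind in (MEAN_BMI, PREV_OBESITY):
        return ("urbanisation",)
    if outcome_kind in (MEAN_SBP, PREV_RAISED_BP):
        return ("urbanisation", "education", "food_availability")
    return ("urbanisation", "education", "food_availability", "mean_bmi")


@dataclass(frozen=True)
class ModelConfig:
    """Structural and prior settings for one outcome and sex."""

    outcome_kind: str = PREV_DIABETES
    year_center: float = 1997.0
    age_knots: tuple[float, ...] = (35.0, 50.0, 65.0)
    ref_age: float = 45.0
    age_range: tuple[float, float] = (15.0, 90.0)
    covariates: tuple[str, ...] | None = None
    prior_fixed_sd: float = 10.0
    prior_sd_scale: float = 1.0

    def __post_init__(self) -> None:
        validate_outcome(self.outcome_kind)
        if self.prior_fixed_sd <= 0 or self.prior_sd_scale <= 0:
            raise ValueError("prior scales must be positive")
        if self.covariates is None:
            object.__setattr__(self, "covariates",
                               default_covariates(self.outcome_kind))

    def describe(self) -> str:
        """Human-readable generative specification for audit."""
        lines = [
            f"outcome: {self.outcome_kind}",
            f"transform: {'logit' if self.outcome_kind.startswith('prev_') else 'identity'}",
            f"year centred at {self.year_center}",
            f"age curve: cubic B-spline, knots {self.age_knots}, "
            f"pinned to 0 at age {self.ref_age}, range {self.age_range}",
            f"covariates (standardised): {', '.join(self.covariates) or 'none'}",
            "hierarchy: global -> region -> country intercepts and slopes",
            "time deviation: per-country RW2, sum-to-zero and zero-linear-trend",
            "coverage fixed effects: delta_sub, delta_comm (national = 0); "
            "urbanisation effect on (study - country) urban fraction; "
            "rural-only and urban-only fixed effects",
            f"priors: fixed effects Normal(0, {self.prior_fixed_sd}^2); "
            f"all SDs half-Normal(0, {self.prior_sd_scale}^2)",
            "likelihood: transformed value ~ Normal(eta, sampling var + "
            "tau_class^2), tau by coverage class",
        ]
        return "\n".join(lines)


class ParameterLayout:
    """Index map between the flat parameter vector and named blocks."""

    def __init__(self, hierarchy: RegionHierarchy, config: ModelConfig):
        self.hierarchy = hierarchy
        self.config = config
        self.countries = hierarchy.countries
        self.regions = hierarchy.regions
        self.region_index = {r: i for i, r in enumerate(self.regions)}
        self.country_index = {c: i for i, c in enumerate(self.countries)}
        self.country_region = np.array(
            [self.region_index[hierarchy.region_of[c]] for c in self.countries])
        self.rw2 = RW2Basis(hierarchy.n_years)
        self.age = AgeBasis(config.age_knots, config.ref_age, config.age_range)
        C, R = len(self.countries), len(self.regions)
        K, W, P = self.age.n_basis, self.rw2.n_free, len(config.covariates)
        self.n_countries, self.n_regions = C, R
        self.n_age_basis, self.n_rw2, self.n_cov = K, W, P

        names: list[tuple[str, int]] = [
            ("g0", 1), ("g1", 1),
            ("region_int", R), ("region_slope", R),
            ("country_int", C), ("country_slope", C),
            ("rw2", C * W),
            ("age_global", K), ("age_country", C * K),
            ("cov", P),
            ("delta_sub", 1), ("delta_comm", 1), ("delta_urb", 1),
            ("delta_rural", 1), ("delta_urban", 1),
        ]
        self.slices: dict[str, slice] = {}
        start = 0
        for name, size in names:
            self.slices[name] = slice(start, start + size)
            start += size
        self.n_coef = start
        self.n_sd = len(SD_NAMES)
        self.n_params = self.n_coef + self.n_sd

    # ---- design rows -----------------------------------------------------
    def design_matrix(self, country_idx: np.ndarray, years: np.ndarray,
                      age_mid: np.ndarray, cov: np.ndarray,
                      coverage_code: np.ndarray, urban_dev: np.ndarray,
                      rural_only: np.ndarray, urban_only: np.ndarray) -> np.ndarray:
        """Dense design matrix mapping the coefficient vector to predictors."""
        n = len(country_idx)
        yc = np.asarray(years, dtype=float) - self.config.year_center
        A = np.zeros((n, self.n_coef))
        sl = self.slices
        rows = np.arange(n)
        A[:, sl["g0"]] = 1.0
        A[:, sl["g1"]] = yc[:, None]
        reg = self.country_region[country_idx]
        A[rows, sl["region_int"].start + reg] = 1.0
        A[rows, sl["region_slope"].start + reg] = yc
        A[rows, sl["country_int"].start + country_idx] = 1.0
        A[rows, sl["country_slope"].start + country_idx] = yc
        t_idx = self.hierarchy.year_index(years)
        W = self.n_rw2
        zrows = self.rw2.Z[t_idx]                      # n x W
        base = sl["rw2"].start + country_idx * W
        for j in range(W):
            A[rows, base + j] = zrows[:, j]
        B = self.age.design(age_mid)                   # n x K
        K = self.n_age_basis
        A[:, sl["age_global"]] = B
        abase = sl["age_country"].start + country_idx * K
        for j in range(K):
            A[rows, abase + j] = B[:, j]
        if self.n_cov:
            A[:, sl["cov"]] = cov
        A[:, sl["delta_sub"]] = (coverage_code == 1)[:, None]
        A[:, sl["delta_comm"]] = (coverage_code == 2)[:, None]
        A[:, sl["delta_urb"]] = np.asarray(urban_dev, dtype=float)[:, None]
        A[:, sl["delta_rural"]] = np.asarray(rural_only, dtype=float)[:, None]
        A[:, sl["delta_urban"]] = np.asarray(urban_only, dtype=float)[:, None]
        return A

    def grid_design(self, cov_lookup) -> tuple[np.ndarray, pd.DataFrame]:
        """Design matrix over the full national (country, year, band) grid.

        ``cov_lookup(country, year) -> standardised covariate row``.
        Returns the matrix and a frame of grid coordinates in row order.
        """
        h = self.hierarchy
        min_age = MIN_AGE[self.config.outcome_kind]
        bands = [b for b in h.age_bands if b.lo >= min_age]
        recs = []
        for ci, c in enumerate(self.countries):
            for y in h.years:
                for b in bands:
                    recs.append((ci, c, int(y), b))
        ci = np.array([r[0] for r in recs])
        yr = np.array([r[2] for r in recs])
        am = np.array([r[3].midpoint for r in recs])
        if self.n_cov:
            cov = np.array([cov_lookup(r[1], r[2]) for r in recs], dtype=float)
        else:
            cov = np.zeros((len(recs), 0))
        zeros = np.zeros(len(recs))
        A = self.design_matrix(ci, yr, am, cov, zeros.astype(int), zeros,
                               zeros, zeros)
        coords = pd.DataFrame({
            "country": [r[1] for r in recs], "year": yr,
            "age_lo": [r[3].lo for r in recs],
            "age_hi": [np.nan if r[3].hi is None else r[3].hi for r in recs],
            "age_mid": am,
        })
        return A, coords


@dataclass
class ParameterState:
    """One full set of model unknowns (named views of the flat vector)."""

    layout: ParameterLayout = field(repr=False)
    coef: np.ndarray            # flat coefficient vector (layout.n_coef)
    sds: np.ndarray             # SD vector in SD_NAMES order

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.coef.shape != (self.layout.n_coef,):
            raise ValueError("coefficient vector has wrong length")
        if self.sds.shape != (self.layout.n_sd,):
            raise ValueError("SD vector has wrong length")

    @classmethod
    def zeros(cls, layout: ParameterLayout, sd: float = 0.1) -> "ParameterState":
        return cls(layout, np.zeros(layout.n_coef), np.full(layout.n_sd, sd))

    def block(self, name: str) -> np.ndarray:
        return self.coef[self.layout.slices[name]]

    def sd(self, name: str) -> float:
        return float(self.sds[SD_NAMES.index(name)])

    @property
    def delta_sub(self) -> float:
        return float(self.block("delta_sub")[0])

    @property
    def delta_comm(self) -> float:
        return float(self.block("delta_comm")[0])

    @property
    def delta_urb(self) -> float:
        return float(self.block("delta_urb")[0])

    def rw2_series(self) -> np.ndarray:
        """Constrained RW2 deviations, shape (n_countries, n_years)."""
        W = self.layout.n_rw2
        w = self.block("rw2").reshape(self.layout.n_countries, W)
        return w @ self.layout.rw2.Z.T

    def tau(self) -> np.ndarray:
        """Study random-effect SDs in coverage-class code order."""
        return np.array([self.sd("tau_national"), self.sd("tau_subnational"),
                         self.sd("tau_community")])

    def copy(self) -> "ParameterState":
        return ParameterState(self.layout, self.coef.copy(), self.sds.copy())


# ---------------------------------------------------------------------------
# model data
# ---------------------------------------------------------------------------

@dataclass
class CovariateStandardizer:
    """Standardise country-year covariates to mean 0, SD 1."""

    names: tuple[str, ...]
    mean: np.ndarray
    scale: np.ndarray
    table: dict  # (country, year) -> raw value row

    @classmethod
    def fit(cls, covariates: pd.DataFrame | None,
            names: Sequence[str]) -> "CovariateStandardizer":
        names = tuple(names)
        if not names:
            return cls(names, np.zeros(0), np.ones(0), {})
        if covariates is None:
            raise ValueError(f"model needs covariates {names} but none supplied")
        wide = covariates.pivot_table(index=["country", "year"],
                                      columns="covariate", values="value")
        missing = [n for n in names if n not in wide.columns]
        if missing:
            raise ValueError(f"covariate table lacks {missing}")
        wide = wide[list(names)]
        mean = wide.mean().to_numpy()
        scale = wide.std(ddof=0).replace(0.0, 1.0).to_numpy()
        table = {idx: row.to_numpy(dtype=float) for idx, row in wide.iterrows()}
        return cls(names, mean, scale, table)

    def __call__(self, country: str, year: int) -> np.ndarray:
        if not self.names:
            return np.zeros(0)
        raw = self.table[(country, int(year))]
        return (raw - self.mean) / self.scale


@dataclass
class ModelData:
    """Validated, model-ready arrays for one outcome and sex."""

    layout: ParameterLayout
    config: ModelConfig
    A: np.ndarray               # n_obs x n_coef design matrix
    y: np.ndarray               # transformed observed values
    sampling_var: np.ndarray    # delta-method sampling variances
    coverage_code: np.ndarray   # 0 national / 1 subnational / 2 community
    standardizer: CovariateStandardizer
    frame: pd.DataFrame         # original observation rows, aligned with A

    @property
    def n_obs(self) -> int:
        return len(self.y)


def build_model_data(surveys: pd.DataFrame, hierarchy: RegionHierarchy,
                     covariates: pd.DataFrame | None,
                     config: ModelConfig) -> ModelData:
    """Assemble design matrix and transformed observations for one sex."""
    layout = ParameterLayout(hierarchy, config)
    df = surveys.reset_index(drop=True)
    kinds = set(df["outcome"].unique())
    if kinds - {config.outcome_kind}:
        raise ValueError(f"survey table mixes outcomes {kinds}")
    sexes = set(df["sex"].unique())
    if len(sexes) > 1:
        raise ValueError("model is fitted separately per sex; "
                         f"table contains {sexes}")
    y = to_transformed(df["value"].to_numpy(), config.outcome_kind)
    bad = ~np.isfinite(y)
    if bad.any():
        rows = df.index[bad].tolist()
        raise ValueError(f"non-finite transformed value for observation rows {rows}")
    svar = observation_variance(df["value"].to_numpy(), df["n"].to_numpy(),
                                config.outcome_kind)
    cov_code = df["coverage"].map(_COVERAGE_CODE).to_numpy()
    std = CovariateStandardizer.fit(covariates, config.covariates)
    c_idx = df["country"].map(layout.country_index)
    if c_idx.isna().any():
        unknown = df.loc[c_idx.isna(), "country"].unique().tolist()
        raise ValueError(f"unknown countries in survey table: {unknown}")
    c_idx = c_idx.to_numpy(dtype=int)
    years = df["year"].to_numpy(dtype=int)
    age_mid = np.array([
        (lo + hi) / 2.0 if np.isfinite(hi) else lo + 5.0
        for lo, hi in zip(df["age_lo"].astype(float), df["age_hi"].astype(float))])
    urb_country = np.array([hierarchy.country_urban_fraction(c, y)
                            for c, y in zip(df["country"], years)])
    uf = df["urban_fraction"].to_numpy(dtype=float)
    urban_dev = np.where(np.isfinite(uf), uf - urb_country, 0.0)
    cov = np.array([std(c, y) for c, y in zip(df["country"], years)],
                   dtype=float).reshape(len(df), layout.n_cov)
    A = layout.design_matrix(c_idx, years, age_mid, cov, cov_code, urban_dev,
                             df["rural_only"].to_numpy(dtype=float),
                             df["urban_only"].to_numpy(dtype=float))
    return ModelData(layout, config, A, y, np.asarray(svar, float), cov_code,
                     std, df)


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

_LOG_2PI = float(np.log(2.0 * np.pi))


def _normal_logpdf(x: np.ndarray, var) -> np.ndarray:
    return -0.5 * (_LOG_2PI + np.log(var)) - 0.5 * np.square(x) / var


def linear_predictor(state: ParameterState, country: str, year: int,
                     age_mid: float, covariates: np.ndarray | None = None,
                     coverage: str = NATIONAL, urban_dev: float = 0.0,
                     rural_only: bool = False, urban_only: bool = False) -> float:
    """Transformed-scale predictor for one (possibly hypothetical) study cell."""
    layout = state.layout
    if country not in layout.country_index:
        raise ValueError(f"unknown country {country!r}")
    if coverage not in COVERAGE_CLASSES:
        raise ValueError(f"unknown coverage class {coverage!r}")
    ci = np.array([layout.country_index[country]])
    cov = (np.asarray(covariates, dtype=float).reshape(1, -1)
           if layout.n_cov else np.zeros((1, 0)))
    if cov.shape[1] != layout.n_cov:
        raise ValueError(f"expected {layout.n_cov} covariate values")
    A = layout.design_matrix(ci, np.array([year]), np.array([age_mid]), cov,
                             np.array([_COVERAGE_CODE[coverage]]),
                             np.array([urban_dev]),
                             np.array([float(rural_only)]),
                             np.array([float(urban_only)]))
    return float(A[0] @ state.coef)


def age_curve(state: ParameterState, country: str, age_mid: float) -> float:
    """Country age effect at an age midpoint; zero at the reference age."""
    layout = state.layout
    if country not in layout.country_index:
        raise ValueError(f"unknown country {country!r}")
    b = layout.age.design(np.array([age_mid]))[0]
    ci = layout.country_index[country]
    K = layout.n_age_basis
    coefs = state.block("age_global") + \
        state.block("age_country")[ci * K:(ci + 1) * K]
    return float(b @ coefs)


def rw2_log_density(u: np.ndarray, sd: float) -> float:
    """RW2 smoothness log density (up to the constraint normalisation).

    Sum of Normal(0, sd^2) log densities of the second differences
    u[t+1] - 2 u[t] + u[t-1].
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 1 or len(u) < 3:
        raise ValueError("RW2 deviation needs at least 3 points")
    if sd <= 0:
        raise ValueError("RW2 SD must be positive")
    d2 = np.diff(u, n=2)
    return float(np.sum(_normal_logpdf(d2, sd * sd)))


def log_likelihood(state: ParameterState, data: ModelData) -> float:
    """Gaussian observation likelihood with coverage-class variance inflation."""
    if data.n_obs == 0:
        return 0.0
    tau = state.tau()
    total_var = data.sampling_var + np.square(tau[data.coverage_code])
    resid = data.y - data.A @ state.coef
    return float(np.sum(_normal_logpdf(resid, total_var)))


def _half_normal_logpdf(x: np.ndarray, scale: float) -> np.ndarray:
    return np.log(2.0) - 0.5 * (_LOG_2PI + 2.0 * np.log(scale)) \
        - 0.5 * np.square(x) / (scale * scale)


def log_prior(state: ParameterState, config: ModelConfig | None = None) -> float:
    """Log prior density up to a constant; -inf for invalid states."""
    layout = state.layout
    config = config or layout.config
    if np.any(state.sds < 0) or not np.all(np.isfinite(state.coef)):
        return -np.inf
    if np.any(state.sds == 0):
        return -np.inf
    lp = 0.0
    fs2 = config.prior_fixed_sd ** 2
    for name in ("g0", "g1", "age_global", "cov", "delta_sub", "delta_comm",
                 "delta_urb", "delta_rural", "delta_urban"):
        lp += float(np.sum(_normal_logpdf(state.block(name), fs2)))
    lp += float(np.sum(_normal_logpdf(state.block("region_int"),
                                      state.sd("sd_region_int") ** 2)))
    lp += float(np.sum(_normal_logpdf(state.block("region_slope"),
                                      state.sd("sd_region_slope") ** 2)))
    lp += float(np.sum(_normal_logpdf(state.block("country_int"),
                                      state.sd("sd_country_int") ** 2)))
    lp += float(np.sum(_normal_logpdf(state.block("country_slope"),
                                      state.sd("sd_country_slope") ** 2)))
    lp += float(np.sum(_normal_logpdf(state.block("age_country"),
                                      state.sd("sd_age_dev") ** 2)))
    for u in state.rw2_series():
        lp += rw2_log_density(u, state.sd("sd_rw2"))
    lp += float(np.sum(_half_normal_logpdf(state.sds, config.prior_sd_scale)))
    return lp


def log_posterior(state: ParameterState, data: ModelData,
                  config: ModelConfig | None = None) -> float:
    lp = log_prior(state, config)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_likelihood(state, data)
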