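"""Parameter-recovery and shrinkage diagnostics against synthetic truth.

Fitting the model to data simulated from a known :class:`TruthSurface`
lets every estimate be compared to its generating value: scalar fixed
effects directly, country-year levels through the transformed-scale
national predictor at the reference age.  The headline metrics are the average absolute bias in posterior
SD units and the empirical coverage of 95% credible intervals across
country-year cells, plus a shrinkage check for a country with no data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimator import HierarchicalTrendModel
from .standards import who_standard
from .summaries import age_standardise, credible_interval
from .synthetic import SurveyDesign, TruthSurface

def truth_age_standardised(truth: TruthSurface, sex: str) -> np.ndarray:
    """Generator's age-standardised surface on the natural scale: (C, T)."""
    standard = who_standard(truth.bands)
    vals = truth.values.sel(sex=sex).values      # (C, T, A)
    return age_standardise(vals, standard)


@dataclass
class RecoveryReport:
    scalar_table: pd.DataFrame     # per-parameter truth/mean/sd/bias
    cell_table: pd.DataFrame       # per country-year cell summaries
    mean_bias_sd: float            # |average signed bias| in posterior SD units
    mean_abs_bias_sd: float        # average |bias|/posterior SD (scalars+cells)
    ci_coverage: float             # fraction of cells covered by the 95% CI
    rmse: float                    # transformed-scale RMSE over cells

    def summary(self) -> str:
        lines = ["parameter recovery report",
                 "-------------------------",
                 f"cells: {len(self.cell_table)}",
                 f"|average bias| (posterior SD units): {self.mean_bias_sd:.3f}",
                 f"mean |bias| (posterior SD units): {self.mean_abs_bias_sd:.3f}",
                 f"95% CI coverage across cells: {self.ci_coverage:.3f}",
                 f"transformed-scale RMSE: {self.rmse:.5f}",
                 "", "scalar parameters:"]
        for row in self.scalar_table.itertuples(index=False):
            lines.append(f"  {row.parameter}: truth={row.truth:+.4f} "
                         f"mean={row.mean:+.4f} sd={row.sd:.4f} "
                         f"bias/sd={row.bias_sd:+.2f}")
        return "\n".join(lines)


def _country_year_levels(model: HierarchicalTrendModel, truth: TruthSurface,
                         sex: str) -> tuple[np.ndarray, np.ndarray]:
    """Transformed-scale country-year levels for draws and truth.

    Evaluates the national linear predictor at the reference age (where
    the pinned age curve vanishes) with the country's covariates:
    draws shaped (n_draws, C, T) and the matching truth grid (C, T).
    """
    layout = model.layout_
    h = model.hierarchy_
    C, T = layout.n_countries, h.n_years
    ci = np.repeat(np.arange(C), T)
    yr = np.tile(h.years, C)
    ages = np.full(C * T, layout.config.ref_age)
    std = model.data_.standardizer
    cov = np.array([std(layout.countries[c], y) for c, y in zip(ci, yr)],
                   dtype=float).reshape(C * T, layout.n_cov)
    zeros = np.zeros(C * T)
    A = layout.design_matrix(ci, yr, ages, cov, zeros.astype(int), zeros,
                             zeros, zeros)
    draws = (model.draws_.coef_matrix() @ A.T).reshape(-1, C, T)
    eta_truth = (A @ truth.states[sex].coef).reshape(C, T)
    return draws, eta_truth


def recovery_report(model: HierarchicalTrendModel, truth: TruthSurface,
                    design: SurveyDesign, sex: str,
                    exclude_countries: tuple[str, ...] = ()) -> RecoveryReport:
    """Compare a fitted posterior to the generating truth for one sex."""
    draws = model.draws_
    truth_scalars = {"g1": truth.states[sex].block("g1")[0],
                     "delta_sub": design.delta_sub,
                     "delta_urb": design.delta_urb}
    srows = []
    for name, tval in truth_scalars.items():
        col = draws.column(name)
        sd = float(col.std(ddof=1))
        srows.append({"parameter": name, "truth": float(tval),
                      "mean": float(col.mean()), "sd": sd,
                      "bias_sd": (float(col.mean()) - float(tval)) / sd})
    scalar_table = pd.DataFrame(srows)

    # country-year levels on the transformed (modelling) scale: the
    # national predictor at the reference age, where the age curve is
    # pinned to zero, so the comparison is linear in the parameters
    eta_draws, eta_truth = _country_year_levels(model, truth, sex)
    layout = model.layout_
    crows = []
    for ci, country in enumerate(layout.countries):
        if country in exclude_countries:
            continue
        for ti, year in enumerate(model.hierarchy_.years):
            d = eta_draws[:, ci, ti]
            lo, hi = credible_interval(d)
            mean, sd = float(d.mean()), float(d.std(ddof=1))
            tval = float(eta_truth[ci, ti])
            crows.append({"country": country, "year": int(year),
                          "truth": tval, "mean": mean, "sd": sd,
                          "lo": lo, "hi": hi,
                          "bias": mean - tval,
                          "bias_sd": (mean - tval) / sd,
                          "covered": lo <= tval <= hi})
    cell_table = pd.DataFrame(crows)
    all_bias = np.concatenate([scalar_table["bias_sd"], cell_table["bias_sd"]])
    return RecoveryReport(
        scalar_table, cell_table,
        mean_bias_sd=float(abs(all_bias.mean())),
        mean_abs_bias_sd=float(np.abs(all_bias).mean()),
        ci_coverage=float(cell_table["covered"].mean()),
        rmse=float(np.sqrt(np.mean(np.square(cell_table["bias"])))),
    )


@dataclass
class ShrinkageReport:
    holdout: str
    mean_dist_sd: float        # |holdout mean - region mean| in posterior SDs
    holdout_ci_width: float    # mean CI width across years
    max_datarich_ci_width: float

    @property
    def pulled_to_region(self) -> bool:
        return self.mean_dist_sd <= 1.0

    @property
    def wider_than_datarich(self) -> bool:
        return self.holdout_ci_width > self.max_datarich_ci_width


def region_line_draws(model: HierarchicalTrendModel, country: str) -> np.ndarray:
    """Age-standardised draws of the region-level trajectory for a country.

    The region line is the model's shrinkage target for a data-free
    country: the predictor with that country's own deviations (intercept,
    slope, RW2, age deviations) set to zero, evaluated with the country's
    covariates, then age-standardised per draw.  Shape (n_draws, n_years).
    """
    layout = model.layout_
    from .outcomes import MIN_AGE, from_transformed

    A_grid, coords = layout.grid_design(model.data_.standardizer)
    mask = (coords["country"] == country).to_numpy()
    A_sel = A_grid[mask].copy()
    sl = layout.slices
    ci = layout.country_index[country]
    W, K = layout.n_rw2, layout.n_age_basis
    for cols in (np.array([sl["country_int"].start + ci]),
                 np.array([sl["country_slope"].start + ci]),
                 np.arange(sl["rw2"].start + ci * W, sl["rw2"].start + (ci + 1) * W),
                 np.arange(sl["age_country"].start + ci * K,
                           sl["age_country"].start + (ci + 1) * K)):
        A_sel[:, cols] = 0.0
    eta = model.draws_.coef_matrix() @ A_sel.T
    nat = np.asarray(from_transformed(eta, layout.config.outcome_kind))
    min_age = MIN_AGE[layout.config.outcome_kind]
    bands = tuple(b for b in model.hierarchy_.age_bands if b.lo >= min_age)
    nat = nat.reshape(model.draws_.n_draws, model.hierarchy_.n_years, len(bands))
    return age_standardise(nat, who_standard(bands))


def shrinkage_report(model: HierarchicalTrendModel,
                     holdout_country: str) -> ShrinkageReport:
    """Check hierarchical shrinkage for a country with no observations.

    The data-free country's posterior mean trajectory should track the
    region's mean trajectory — the model's region line, its shrinkage
    target — within one posterior SD on average, while carrying wider
    credible intervals than any data-rich country in the same region.
    """
    layout = model.layout_
    h = model.hierarchy_
    asd = model.country_year_posterior()
    region = h.region_of[holdout_country]
    members = h.countries_in(region)
    hold_i = layout.country_index[holdout_country]
    others = [layout.country_index[c] for c in members if c != holdout_country]

    hold_mean = asd[:, hold_i, :].mean(axis=0)
    hold_sd = asd[:, hold_i, :].std(axis=0, ddof=1)
    region_mean = region_line_draws(model, holdout_country).mean(axis=0)
    dist = np.abs(hold_mean - region_mean) / hold_sd

    def mean_width(ci: int) -> float:
        widths = [np.subtract(*reversed(credible_interval(asd[:, ci, t])))
                  for t in range(asd.shape[2])]
        return float(np.mean(widths))

    return ShrinkageReport(
        holdout=holdout_country,
        mean_dist_sd=float(dist.mean()),
        holdout_ci_width=mean_width(hold_i),
        max_datarich_ci_width=max(mean_width(i) for i in others),
    )


@dataclass
class RecoveryExperiment:
    """Results of the default two-sex recovery + shrinkage experiment."""

    reports: dict                   # sex -> RecoveryReport
    shrinkage: dict                 # sex -> ShrinkageReport
    models: dict                    # sex -> fitted estimator
    truth: TruthSurface
    design: SurveyDesign

    @property
    def mean_bias_sd(self) -> float:
        pooled = np.concatenate([
            np.concatenate([r.scalar_table["bias_sd"], r.cell_table["bias_sd"]])
            for r in self.reports.values()])
        return float(abs(pooled.mean()))

    @property
    def ci_coverage(self) -> float:
        cov = [r.cell_table["covered"] for r in self.reports.values()]
        return float(pd.concat(cov).mean())


def run_default_recovery(seed: int = 1, sexes=("men", "women"),
                         n_chains: int = 4, n_iter: int = 4000,
                         burn_in: int = 1000) -> RecoveryExperiment:
    """Run the default synthetic recovery experiment end to end.

    12 countries in 3 regions, 10 studies per data-rich country, one
    hold-out country with no data; the model is fitted separately per sex
    with the small test schedule and compared to the generating truth.
    """
    from .synthetic import HOLDOUT_COUNTRY, default_recovery_scenario, \
        generate_covariates, generate_truth, sample_surveys

    h, settings, design = default_recovery_scenario(seed=seed)
    covariates = generate_covariates(h, tuple(settings.covariate_effects),
                                     seed=seed)
    truth = generate_truth(h, settings, "prev_diabetes", seed=seed,
                           covariates=covariates)
    surveys = sample_surveys(truth, design, seed=seed)
    reports, shrink, models = {}, {}, {}
    for k, sex in enumerate(sexes):
        model = HierarchicalTrendModel(
            outcome_kind="prev_diabetes",
            covariates=tuple(settings.covariate_effects),
            n_chains=n_chains, n_iter=n_iter, burn_in=burn_in,
            seed=seed * 101 + k)
        model.fit(surveys[surveys["sex"] == sex], hierarchy=h,
                  covariates=covariates)
        reports[sex] = recovery_report(model, truth, design, sex)
        shrink[sex] = shrinkage_report(model, HOLDOUT_COUNTRY)
        models[sex] = model
    return RecoveryExperiment(reports, shrink, models, truth, design)


def validation_table(estimates: pd.DataFrame, truth_frame: pd.DataFrame,
                     standard_bands) -> pd.DataFrame:
    """Join a country-level estimate table with age-standardised truth.

    ``truth_frame`` is the generator's per-band truth CSV; it is
    age-standardised with the WHO weights before joining.
    """
    standard = who_standard(standard_bands)
    labels = [b.label for b in standard.bands]
    wide = truth_frame.pivot_table(index=["country", "year", "sex"],
                                   columns="age_group", values="value")
    wide = wide[labels]
    asd = wide.to_numpy() @ standard.weight_array()
    truth_asd = wide.reset_index()[["country", "year", "sex"]]
    truth_asd["truth"] = asd
    merged = estimates[estimates["level"] == "country"].merge(
        truth_asd, left_on=["entity", "year", "sex"],
        right_on=["country", "year", "sex"], how="inner")
    merged["bias"] = merged["mean"] - merged["truth"]
    merged["covered"] = (merged["lo"] <= merged["truth"]) & \
        (merged["truth"] <= merged["hi"])
    return merged[["entity", "year", "sex", "truth", "mean", "lo", "hi",
                   "bias", "covered"]]
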