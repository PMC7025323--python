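"""Posterior summarisation: age-standardised estimates, regional
aggregates, credible intervals, probabilities and ratios of change, and
rank correlations between risk factors.

All draw-level operations are applied on the natural scale, draw by draw,
before any summarisation, so credible intervals propagate the full
posterior uncertainty of the non-linear transform and the aggregation
weights.
"""

from __future__ import annotations

import decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hierarchy import RegionHierarchy
from .outcomes import from_transformed
from .sampler import PosteriorDraws
from .standards import StandardPopulation, who_standard


def age_standardise(values: np.ndarray, standard: StandardPopulation,
                    bands=None) -> np.ndarray:
    """Weighted sum of age-specific values over the standard's bands.

    ``values`` may carry extra leading dimensions (draws, years); the
    trailing dimension must match the standard's bands.  When ``bands`` is
    given it is checked against the standard's bands and mismatches are
    reported.
    """
    w = standard.weight_array()
    values = np.asarray(values, dtype=float)
    if bands is not None:
        unmatched = [b.label for b, s in zip(bands, standard.bands)
                     if (b.lo, b.hi) != (s.lo, s.hi)]
        unmatched += [s.label for s in standard.bands[len(bands):]]
        unmatched += [b.label for b in tuple(bands)[len(standard.bands):]]
        if unmatched:
            raise ValueError(f"age bands do not match the standard "
                             f"population: {unmatched}")
    if values.shape[-1] != len(w):
        raise ValueError(f"expected {len(w)} age bands, got {values.shape[-1]}")
    return values @ w


def aggregate_region(country_values: np.ndarray,
                     populations: np.ndarray) -> np.ndarray:
    """Population-weighted mean of country values (draw-wise).

    ``country_values`` has countries on the trailing axis; ``populations``
    are the matching (country, year) adult populations.
    """
    pop = np.asarray(populations, dtype=float)
    if np.any(~np.isfinite(pop)) or np.any(pop <= 0):
        raise ValueError("populations must be positive and finite")
    vals = np.asarray(country_values, dtype=float)
    if vals.shape[-1] != len(pop):
        raise ValueError("one population weight per country required")
    return vals @ (pop / pop.sum())


def credible_interval(draws: np.ndarray, lo: float = 2.5,
                      hi: float = 97.5) -> tuple[float, float]:
    """Empirical (2.5th, 97.5th) percentile interval with linear
    interpolation between order statistics."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 40:
        raise ValueError("credible interval needs at least 40 draws")
    q = np.percentile(draws, [lo, hi], method="linear")
    return float(q[0]), float(q[1])


def prob_change(draws_t0: np.ndarray, draws_t1: np.ndarray) -> float:
    """Posterior probability of an increase between two matched years.

    The proportion of matched draws with value(t1) > value(t0); exact ties
    count one half.
    """
    a = np.asarray(draws_t0, dtype=float)
    b = np.asarray(draws_t1, dtype=float)
    if a.shape != b.shape:
        raise ValueError("draw vectors must be matched by index")
    return float(np.mean((b > a) + 0.5 * (b == a)))


def change_ratio(value_t1: float, value_t0: float, decimals: int = 1) -> float:
    """Ratio of a later to an earlier value, rounded half away from zero."""
    if value_t0 <= 0:
        raise ValueError("the earlier value must be positive")
    ratio = decimal.Decimal(repr(float(value_t1))) / decimal.Decimal(repr(float(value_t0)))
    quant = decimal.Decimal(1).scaleb(-decimals)
    return float(ratio.quantize(quant, rounding=decimal.ROUND_HALF_UP))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# estimate tables
# ---------------------------------------------------------------------------

def _grid_draw_matrix(draws: PosteriorDraws, standardizer) -> tuple:
    """Natural-scale draw values over the national grid.

    Returns (values with shape (n_draws, C, T, A), coords frame, bands).
    """
    layout = draws.layout
    A_grid, coords = layout.grid_design(standardizer)
    eta = draws.coef_matrix() @ A_grid.T          # (n_draws, n_cells)
    nat = from_transformed(eta, layout.config.outcome_kind)
    n_bands = coords.groupby(["country", "year"]).size().iloc[0]
    C = layout.n_countries
    T = layout.hierarchy.n_years
    return np.asarray(nat).reshape(draws.n_draws, C, T, n_bands), coords, n_bands


def country_year_draws(draws: PosteriorDraws, hierarchy: RegionHierarchy,
                       standard: StandardPopulation | None = None,
                       standardizer=None) -> np.ndarray:
    """Age-standardised country-year values per draw: (n_draws, C, T)."""
    layout = draws.layout
    std = standardizer if standardizer is not None else (lambda c, y: np.zeros(0))
    nat, coords, n_bands = _grid_draw_matrix(draws, std)
    if standard is None:
        from .outcomes import MIN_AGE
        min_age = MIN_AGE[layout.config.outcome_kind]
        bands = tuple(b for b in hierarchy.age_bands if b.lo >= min_age)
        standard = who_standard(bands)
    return age_standardise(nat, standard)


def build_estimate_table(draws: PosteriorDraws, hierarchy: RegionHierarchy,
                         standard: StandardPopulation | None = None,
                         standardizer=None) -> pd.DataFrame:
    """Country- and region-level age-standardised posterior summaries.

    One row per (entity, level, year): posterior mean and the 2.5th/97.5th
    percentile credible interval of the age-standardised outcome, with
    regions aggregated draw-by-draw using adult population weights.
    """
    layout = draws.layout
    asd = country_year_draws(draws, hierarchy, standard, standardizer)
    outcome = layout.config.outcome_kind
    rows = []

    def summarise(entity, level, series):  # series: (n_draws, T)
        for j, year in enumerate(hierarchy.years):
            d = series[:, j]
            lo, hi = (credible_interval(d) if len(d) >= 40
                      else (float(d.min()), float(d.max())))
            rows.append((entity, level, int(year), outcome,
                         float(d.mean()), lo, hi))

    for ci, country in enumerate(layout.countries):
        summarise(country, "country", asd[:, ci, :])
    for region in hierarchy.regions:
        idx = [layout.country_index[c] for c in hierarchy.countries_in(region)]
        pops = np.array([[hierarchy.adult_population(hierarchy.countries[i], y)
                          for i in idx] for y in hierarchy.years])  # (T, k)
        weights = pops / pops.sum(axis=1, keepdims=True)
        series = np.einsum("dct,tc->dt", asd[:, idx, :], weights)
        summarise(region, "region", series)
    df = pd.DataFrame(rows, columns=["entity", "level", "year", "outcome",
                                     "mean", "lo", "hi"])
    return df


def change_summary(draws: PosteriorDraws, hierarchy: RegionHierarchy,
                   year0: int | None = None, year1: int | None = None,
                   standard: StandardPopulation | None = None,
                   standardizer=None) -> pd.DataFrame:
    """Per-country probability of increase and change ratio between two years."""
    year0 = int(hierarchy.years[0]) if year0 is None else year0
    year1 = int(hierarchy.years[-1]) if year1 is None else year1
    j0, j1 = hierarchy.year_index(year0), hierarchy.year_index(year1)
    asd = country_year_draws(draws, hierarchy, standard, standardizer)
    rows = []
    for ci, country in enumerate(draws.layout.countries):
        d0, d1 = asd[:, ci, j0], asd[:, ci, j1]
        rows.append((country, year0, year1,
                     prob_change(d0, d1),
                     change_ratio(float(d1.mean()), float(d0.mean()))))
    return pd.DataFrame(rows, columns=["entity", "year0", "year1",
                                       "prob_increase", "change_ratio"])
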