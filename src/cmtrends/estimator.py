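"""Scikit-learn style front end to the hierarchical trend model.

:class:`HierarchicalTrendModel` wraps model construction, MCMC fitting
and posterior summarisation behind the familiar ``fit`` / ``predict``
surface: hyperparameters are constructor arguments (so the estimator
composes with ``get_params``/``set_params`` and sklearn model selection),
``fit`` consumes a validated single-sex survey table, and fitted state
lives in trailing-underscore attributes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .hierarchy import RegionHierarchy
from .model import ModelConfig, build_model_data
from .sampler import MCMCSchedule, combine_and_thin, convergence_summary, \
    run_chain
from .standards import StandardPopulation
from .summaries import build_estimate_table, change_summary, \
    country_year_draws

RHAT_WARN = 1.1


class HierarchicalTrendModel(BaseEstimator):
    """Bayesian hierarchical country-year-age trend model for one outcome.

    Parameters
    ----------
    outcome_kind : one of the five supported outcomes (mean BMI, mean SBP,
        obesity / raised blood pressure / diabetes prevalence).
    covariates : country-level covariate names, or None for the
        per-outcome defaults.
    age_knots, ref_age : interior B-spline knots and the pin age of the
        country-varying age curve.
    prior_fixed_sd, prior_sd_scale : normal prior SD for fixed effects and
        half-normal scale for all variance components.
    n_chains, n_iter, burn_in, per_chain_size, final_size, seed :
        MCMC schedule (defaults are the small test schedule; the
        production schedule is 20 chains of 55 000 iterations).

    Attributes (after fit)
    ----------------------
    draws_ : :class:`~cmtrends.sampler.PosteriorDraws`
    rhat_ : dict of split R-hat values for monitored scalars
    acceptance_ : per-block acceptance rates, per chain
    data_, layout_, config_ : model internals for downstream summaries
    """

    def __init__(self, outcome_kind: str = "prev_diabetes",
                 covariates: tuple[str, ...] | None = None,
                 year_center: float = 1997.0,
                 age_knots: tuple[float, ...] = (35.0, 50.0, 65.0),
                 ref_age: float = 45.0,
                 prior_fixed_sd: float = 10.0, prior_sd_scale: float = 1.0,
                 n_chains: int = 4, n_iter: int = 4000, burn_in: int = 1000,
                 per_chain_size: int = 500, final_size: int | None = None,
                 seed: int = 0):
        self.outcome_kind = outcome_kind
        self.covariates = covariates
        self.year_center = year_center
        self.age_knots = age_knots
        self.ref_age = ref_age
        self.prior_fixed_sd = prior_fixed_sd
        self.prior_sd_scale = prior_sd_scale
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.per_chain_size = per_chain_size
        self.final_size = final_size
        self.seed = seed

    # ------------------------------------------------------------------
    def _config(self) -> ModelConfig:
        return ModelConfig(outcome_kind=self.outcome_kind,
                           year_center=self.year_center,
                           age_knots=tuple(self.age_knots),
                           ref_age=self.ref_age,
                           covariates=(tuple(self.covariates)
                                       if self.covariates is not None else None),
                           prior_fixed_sd=self.prior_fixed_sd,
                           prior_sd_scale=self.prior_sd_scale)

    def schedule(self) -> MCMCSchedule:
        return MCMCSchedule(n_chains=self.n_chains, n_iter=self.n_iter,
                            burn_in=self.burn_in,
                            per_chain_size=self.per_chain_size,
                            final_size=self.final_size, seed=self.seed)

    def fit(self, X: pd.DataFrame, y=None, *, hierarchy: RegionHierarchy,
            covariates: pd.DataFrame | None = None) -> "HierarchicalTrendModel":
        """Fit the posterior by MCMC on a single-sex survey table."""
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a survey observation DataFrame")
        self.config_ = self._config()
        self.data_ = build_model_data(X, hierarchy, covariates, self.config_)
        self.layout_ = self.data_.layout
        self.hierarchy_ = hierarchy
        sched = self.schedule()
        results = [run_chain(self.data_, sched, k)
                   for k in range(sched.n_chains)]
        self.draws_ = combine_and_thin(results, layout=self.layout_)
        self.rhat_ = (convergence_summary(results, self.layout_)
                      if sched.n_chains >= 2 else {})
        self.acceptance_ = self.draws_.acceptance
        self.max_rhat_ = max(self.rhat_.values()) if self.rhat_ else float("nan")
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "draws_"):
            raise RuntimeError("model is not fitted; call fit() first")

    def estimate_table(self, standard: StandardPopulation | None = None
                       ) -> pd.DataFrame:
        """Country and region age-standardised posterior mean and 95% CI."""
        self._check_fitted()
        return build_estimate_table(self.draws_, self.hierarchy_, standard,
                                    self.data_.standardizer)

    def change_table(self, year0: int | None = None, year1: int | None = None
                     ) -> pd.DataFrame:
        self._check_fitted()
        return change_summary(self.draws_, self.hierarchy_, year0, year1,
                              standardizer=self.data_.standardizer)

    def country_year_posterior(self, standard: StandardPopulation | None = None
                               ) -> np.ndarray:
        """Age-standardised draws, shape (n_draws, n_countries, n_years)."""
        self._check_fitted()
        return country_year_draws(self.draws_, self.hierarchy_, standard,
                                  self.data_.standardizer)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior-mean age-standardised outcome for (country, year) rows."""
        self._check_fitted()
        asd = self.country_year_posterior().mean(axis=0)
        ci = X["country"].map(self.layout_.country_index)
        if ci.isna().any():
            raise ValueError(f"unknown countries: "
                             f"{X.loc[ci.isna(), 'country'].unique().tolist()}")
        ti = self.hierarchy_.year_index(X["year"].to_numpy())
        return asd[ci.to_numpy(dtype=int), ti]
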