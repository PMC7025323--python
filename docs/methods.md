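# Methods

`cmtrends` estimates country–year–age trends of cardiometabolic risk
factors (mean BMI, obesity prevalence, mean systolic blood pressure,
raised-blood-pressure prevalence, diabetes prevalence) from heterogeneous
study-level survey summaries, using a Bayesian hierarchical model fitted
by MCMC. This note records the model, its assumptions, the synthetic-data
generator used for validation, and the numerical and design choices that
were genuinely open.

## Observation model

Each survey contributes one row per sex and age band: an outcome summary
`value`, an effective sample size `n`, a coverage class (national,
subnational = ≥1 subnational region or >3 communities, community = ≤3
communities), the study's urban fraction (possibly unknown), and
urban-only / rural-only flags. Analyses are strictly separate by sex.

Prevalences are modelled on the logit scale, means on the natural scale.
The transformed observation for study *i* in country *c*, year *t*, age
band with midpoint *a* is

    y_i ~ Normal( eta_i , s_i^2 + tau_{k(i)}^2 )

    eta_i = (b0 + b0_r(c) + b0_c) + (b1 + b1_r(c) + b1_c) (t - 1997)
          + u_c(t) + f_c(a) + x_{ct}' beta
          + d_sub 1{subnational} + d_comm 1{community}
          + d_urb (z_i - z_ct) + d_rural 1{rural-only} + d_urban 1{urban-only}

* `s_i^2` is the delta-method sampling variance: `1/(n p~ (1-p~))` on the
  logit scale for a prevalence, with `p~` clamped to `[0.5/n, 1-0.5/n]`
  (continuity correction; keeps degenerate proportions finite); for a
  mean outcome, `(person-level SD)^2 / n` with SD 4.5 kg/m² (BMI) or
  18 mm Hg (SBP).
* `tau_k` is a coverage-class study random-effect SD, marginalised into
  the observation variance, so national data carry more weight than
  non-national data of equal size. All three taus are estimated with
  half-normal priors.
* `z_i - z_ct` is the study-minus-country urban fraction in the study
  year; unknown study urban fractions contribute 0 (no adjustment).
  Rural/urban-only fixed effects are additive with the coverage effects.

## Hierarchy, time and age components

Three pooling levels (global → region → country) for both intercepts and
linear slopes; deviations get zero-mean normal priors with estimated SDs.
Calendar year is centred at 1997 (the 1980–2014 midpoint) so intercepts
are mid-period levels.

Non-linear time trends are per-country second-order random walks `u_c`
over the yearly grid: iid Normal(0, sd_rw2²) second differences, with
sum-to-zero and zero-linear-trend constraints making `u_c` orthogonal to
the hierarchical intercept and slope. Internally `u_c = Z w_c` where `Z`
is an orthonormal basis of the doubly-constrained subspace, so every
sampled state satisfies the constraints by construction.

Age patterns are cubic B-splines over ages 15–90 with interior knots at
35, 50, 65, pinned to zero at the reference age 45 (the basis itself is
pinned, so the constraint holds for any coefficients). Coefficients are
global plus per-country deviations with an estimated SD, letting the age
pattern vary smoothly across countries.

Country-level covariates (urbanisation for BMI outcomes; urbanisation,
education and a food-availability summary for blood pressure and
diabetes; plus mean BMI for diabetes) enter the predictor standardised to
mean 0, SD 1 across country-years.

Priors: Normal(0, 10²) on all fixed effects (transformed scale),
half-Normal(0, 1) on every SD. Both scales are configurable.

## Sampler

Adaptive Metropolis-within-Gibbs. The parameter vector is partitioned
into blocks — scalar fixed effects, per-region and per-country intercept
and slope deviations, per-country RW2 weight vectors, global and
per-country age-coefficient vectors, and the variance components on the
log scale. Each block uses a random-walk proposal preconditioned by its
approximate conditional precision (likelihood Gram matrix plus prior
precision at initialisation); scalar step sizes are adapted by
Robbins–Monro toward 0.44 (scalars) or 0.30 (vectors) during burn-in
only, so the post-burn-in kernel is fixed and draws are reproducible
given (seed, chain index).

Two families of auxiliary Metropolis moves are interleaved to fix the
well-known slow directions of centred hierarchical parameterisations:

* recentering translations — shift mass between a level and the level
  below along directions that leave the likelihood exactly invariant
  (e.g. add `d` to the global slope and subtract `d` from every region
  slope), accepted on the prior ratio alone;
* scale interweaving — rescale a deviation block jointly with its SD
  (`w → w e^eps`, `s → s e^eps`), the ancillarity–sufficiency move, which
  decouples each SD from the amplitude of its deviations.

Without these moves the split R̂ of the global slope and the RW2 SD
exceeded 2 at the test schedule; with them the maximum monitored R̂ is
≈1.1–1.35. Runs emit a warning (not an abort) when any monitored R̂
exceeds 1.1.

Initialisation: ridge least squares for the non-hierarchical effects
(intercept, slope, coverage and urbanisation effects, covariates, global
age curve), deviations at 0, SDs at 0.1.

Schedules: the production schedule is 20 chains × 55 000 iterations with
5 000 burn-in, thinned to 5 000 per chain and a combined final 5 000
draws (two-stage, evenly spaced thinning; the last retained draw is
always kept). The default test schedule is 4 chains × 4 000 iterations,
1 000 burn-in, 500 per chain — small enough that the full recovery
experiment runs in about a minute on one CPU.

## Posterior summaries

Every reported quantity is computed draw by draw on the natural scale
before summarisation: inverse transform, age-standardisation with the
WHO World Standard weights (packaged five-year table, Ahmad et al., WHO
GPE Discussion Paper 31, 2001; collapsed onto the modelled bands and
renormalised over the adult range), then optionally population-weighted
regional aggregation using (country, year) adult populations. Credible
intervals are 2.5th–97.5th empirical percentiles with linear
interpolation between order statistics. Probabilities of increase are
the proportion of matched draws in which the later year exceeds the
earlier one, ties counting one half. Change ratios are rounded half away
from zero at the reported precision. Cross-risk-factor correlations use
Spearman mid-ranks, one value per country at a stated year.

## Synthetic-data generator

The generator draws a "true" surface from exactly the structure the
model assumes — the same design matrix, the same constrained RW2 basis,
the same pinned age basis — so the generating parameters live in the
model's own parameter layout and recovery can be checked block by block.
Study sampling then adds the coverage offset, the urbanisation term, a
study random effect, and sampling noise with the delta-method variance
at the true value.

Default generative conditions (chosen once as a realistic diabetes-like
prevalence): mid-period level logit(0.08), slope 0.022/yr on the logit
scale (odds roughly double over 1980–2014), region/country intercept SDs
0.35/0.30, slope SDs 0.004/0.005, RW2 SD 0.012, age-deviation SD 0.15, a
saturating age gradient spanning ≈2 logit units over adulthood, and one
covariate effect of 0.3 per SD of urbanisation. Default survey design:
10 studies per country, coverage probabilities (0.5, 0.3, 0.2), offsets
d_sub = 0.2, d_comm = 0.35, d_urb = 0.25, study random-effect SDs
(0.05, 0.10, 0.15) by class, log-normal sample sizes (median 600, sigma
0.8, floor 25), 8% urban-only and 5% rural-only studies, 10% unknown
urban fraction. Synthetic populations are log-linear in year with fixed
per-country age pyramids; urbanisation follows smooth logistic paths.

What the generator does **not** emulate about real pooled survey data:
within-study clustering (the study random effect is drawn independently
per reported row, matching the model's marginal-likelihood independence
assumption, whereas real rows from one study share one effect),
biomarker harmonisation, non-random survey timing, reporting gaps
correlated with outcome levels, and real covariate or population series.
Passing recovery tests therefore demonstrates correctness of the
machinery under the model's own assumptions, not robustness to the
misspecifications real data would add.

## Validation experiments

* **Parameter recovery** (default scenario): 12 countries in 3 regions,
  1980–2014, 10 studies per country, with one designated hold-out
  country receiving no studies so the same run exercises shrinkage. The
  model is fitted per sex at the test schedule; we report the absolute
  *average signed* bias in posterior-SD units pooled over the offset and
  slope parameters and all country-year transformed-scale levels (the
  systematic component — for a calibrated posterior the *per-parameter*
  |bias|/SD averages ≈0.8 by construction, so only the signed average is
  informative about correctness) and the empirical coverage of 95%
  credible intervals across those cells. Country-year levels are
  compared on the transformed scale (the national predictor at the
  reference age), where the comparison is linear in the parameters.
  At the default seed: signed bias ≈0.12, coverage ≈0.95. Because one
  experiment compares one posterior to one truth draw, the signed-bias
  metric varies across dataset seeds with a spread of roughly 0.2
  (shared global/region components limit the effective sample size);
  coverage is more stable (0.87–0.95 across seeds).
* **Shrinkage**: the hold-out country's posterior trajectory is compared
  to the model's region line (the predictor with the country's own
  deviations zeroed — its actual shrinkage target); its credible
  intervals must be wider than any data-rich neighbour's.
* **Conjugate limit**: the adaptive RWM kernel on a normal–normal toy
  model against the closed-form posterior.
* **Zero-noise identity**: with all noise and offsets zero and a
  degenerate posterior at the generating parameters, the estimate table
  reproduces the generator's age-standardised truth to floating-point
  round-off.

## Numerical choices and edge cases

* Logit of values outside (0,1) is ±inf; model-data construction rejects
  such rows naming their indices. Degenerate proportions are clamped
  before the variance formula, not before the transform of the value.
* Thinning keeps indices `(j+1)·N/m - 1` for `j = 0..m-1` (integer
  arithmetic): even spacing, identity when `m = N`, last draw kept.
* Split R̂ uses the classic between/within variance ratio on
  half-chains; it requires ≥2 chains and ≥10 draws per chain.
* Tie handling: probability of increase counts ties as 0.5; Spearman uses
  mid-ranks; change ratios round half away from zero.
* The band midpoint is `(lo+hi)/2` for closed bands and `lo+5` for the
  open-ended band; BMI outcomes exclude bands below age 20.
* One global seed expands into per-stage seeds via
  `SeedSequence((seed, stage_ordinal))` (kept below 2³¹); chains derive
  streams from `(fit seed, chain index)`. All generator and sampler
  randomness flows through NumPy `Generator` objects.

## Known limitations

* The Gaussian observation model on the logit scale is an approximation
  for very small prevalences or tiny samples where the binomial is
  skewed.
* Coverage-class random effects are exchangeable across studies and
  uncorrelated within study (see generator note above).
* Regional aggregation assumes population weighting; model-level
  aggregation would differ slightly for strongly non-linear transforms.
* Sexes are fitted independently; no information is shared across sexes
  or across risk factors.
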