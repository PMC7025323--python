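"""Adaptive Metropolis-within-Gibbs sampling of the trend model posterior.

The parameter vector is partitioned into blocks (scalar fixed effects,
per-region and per-country deviations, per-country RW2 weight vectors, age
coefficients, and the variance components on the log scale).  Each block
is updated by a random-walk Metropolis step whose proposal covariance is
preconditioned by the block's approximate conditional precision
(likelihood Gram matrix plus prior precision at initialisation) and whose
scalar step size is adapted during burn-in only, so the post-burn-in
kernel is fixed and draws are reproducible given (seed, chain index).

Likelihood evaluations are incremental: the residual vector is cached and
updated from the proposed block's design columns, so one block update
costs O(n_obs * block size) rather than a full predictor rebuild.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import ModelData, ParameterState, SD_NAMES

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class MCMCSchedule:
    """Chain bookkeeping: iterations, burn-in and two-stage thinning."""

    n_chains: int = 4
    n_iter: int = 4000
    burn_in: int = 1000
    per_chain_size: int = 500
    final_size: int | None = None
    seed: int = 0
    adapt_window: int = 50

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_iter < 1:
            raise ValueError("need at least one chain and one iteration")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn-in must be smaller than the iteration count")
        if self.per_chain_size > self.n_iter - self.burn_in:
            raise ValueError("per-chain thinned size exceeds retained iterations")
        if self.final_total > self.n_chains * self.per_chain_size:
            raise ValueError("final size exceeds the combined thinned draws")

    @property
    def retained_iterations(self) -> int:
        """Post-burn-in iterations per chain, before thinning."""
        return self.n_iter - self.burn_in

    @property
    def final_total(self) -> int:
        return (self.final_size if self.final_size is not None
                else self.n_chains * self.per_chain_size)

    @classmethod
    def paper_schedule(cls, seed: int = 0) -> "MCMCSchedule":
        """20 chains of 55 000 iterations, 5 000 burn-in, thinned to 5 000
        per chain and a combined final 5 000 draws."""
        return cls(n_chains=20, n_iter=55_000, burn_in=5_000,
                   per_chain_size=5_000, final_size=5_000, seed=seed)


def thinning_indices(n_available: int, n_keep: int) -> np.ndarray:
    """Evenly spaced retention indices (the last draw is always kept)."""
    if n_keep > n_available:
        raise ValueError(f"cannot keep {n_keep} of {n_available} draws")
    return (np.arange(1, n_keep + 1) * n_available) // n_keep - 1


@dataclass
class PosteriorDraws:
    """Retained, combined posterior samples with provenance."""

    draws: np.ndarray                  # (n_draws, n_params) flat states
    chain: np.ndarray                  # chain index per draw
    param_names: tuple[str, ...]
    schedule: MCMCSchedule
    layout: object = None              # ParameterLayout when model-based
    acceptance: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self.param_names.index(name)]

    def states(self):
        """Iterate draws as :class:`ParameterState` objects."""
        n_coef = self.layout.n_coef
        for row in self.draws:
            yield ParameterState(self.layout, row[:n_coef], row[n_coef:])

    def coef_matrix(self) -> np.ndarray:
        return self.draws[:, :self.layout.n_coef]

    def to_frame(self) -> pd.DataFrame:
        n, p = self.draws.shape
        return pd.DataFrame({
            "chain": np.repeat(self.chain, p),
            "draw": np.repeat(np.arange(n), p),
            "parameter": np.tile(np.asarray(self.param_names, object), n),
            "value": self.draws.ravel(),
        })

    def save(self, csv_path: str | Path, sidecar_path: str | Path,
             rhat: dict | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        meta = {
            "schedule": {k: getattr(self.schedule, k) for k in
                         ("n_chains", "n_iter", "burn_in", "per_chain_size",
                          "final_size", "seed", "adapt_window")},
            "n_draws": int(self.n_draws),
            "acceptance": {k: (list(np.round(v, 4)) if np.ndim(v) else float(v))
                           for k, v in self.acceptance.items()},
            "rhat": rhat or {},
        }
        Path(sidecar_path).write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# adaptive step helper (shared by the block sampler and the generic RWM)
# ---------------------------------------------------------------------------

class _AdaptiveStep:
    """Robbins-Monro adaptation of a log step size toward a target rate."""

    def __init__(self, step: float, target: float, adapt_window: int):
        self.log_step = float(np.log(step))
        self.target = target
        self.window = adapt_window
        self.n_prop = 0
        self.n_acc = 0

    def scale(self) -> float:
        return float(np.exp(self.log_step))

    def update(self, accept_prob: float, iteration: int, adapting: bool) -> None:
        self.n_prop += 1
        if adapting:
            c = 0.25 / np.sqrt(1.0 + iteration / self.window)
            self.log_step += c * (accept_prob - self.target)

    def record(self, accepted: bool) -> None:
        self.n_acc += int(accepted)

    @property
    def rate(self) -> float:
        return self.n_acc / max(self.n_prop, 1)


def adaptive_rwm(logpdf: Callable[[float], float], x0: float, n_iter: int,
                 burn_in: int, seed: int = 0, step: float = 1.0,
                 target: float = 0.44) -> np.ndarray:
    """Generic scalar adaptive random-walk Metropolis (the per-block kernel).

    Used for conjugate-limit checks of the update rule on targets with
    closed-form posteriors; adaptation stops at the end of burn-in.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1234)))
    x = float(x0)
    lp = logpdf(x)
    stepper = _AdaptiveStep(step, target, 50)
    out = np.empty(n_iter - burn_in)
    for t in range(n_iter):
        prop = x + stepper.scale() * rng.standard_normal()
        lp_prop = logpdf(prop)
        alpha = min(1.0, float(np.exp(min(lp_prop - lp, 0.0))))
        if rng.random() < alpha:
            x, lp = prop, lp_prop
        stepper.update(alpha, t, adapting=t < burn_in)
        if t >= burn_in:
            out[t - burn_in] = x
    return out


# ---------------------------------------------------------------------------
# model-posterior chain
# ---------------------------------------------------------------------------

class _Block:
    __slots__ = ("name", "cols", "A", "L", "prior", "stepper", "M")

    def __init__(self, name, cols, A, L, prior, stepper, M=None):
        self.name, self.cols, self.A, self.L = name, cols, A, L
        self.prior, self.stepper, self.M = prior, stepper, M


def _build_blocks(data: ModelData, tau0: float, sd0: float,
                  adapt_window: int) -> list[_Block]:
    layout = data.layout
    sl = layout.slices
    wv0 = 1.0 / (data.sampling_var + tau0 * tau0)
    fs2 = layout.config.prior_fixed_sd ** 2

    def precond(cols: np.ndarray, prior_prec: np.ndarray) -> tuple:
        A_blk = np.ascontiguousarray(data.A[:, cols])
        gram = (A_blk * wv0[:, None]).T @ A_blk + prior_prec
        cov = np.linalg.inv(gram)
        # symmetrise before factorising
        L = np.linalg.cholesky(0.5 * (cov + cov.T))
        return A_blk, L

    blocks: list[_Block] = []

    def add(name, cols, prior, prior_prec, M=None, target=None):
        cols = np.asarray(cols, dtype=int)
        d = len(cols)
        A_blk, L = precond(cols, prior_prec)
        tgt = target if target is not None else (0.44 if d == 1 else 0.30)
        step = 2.38 / np.sqrt(d)
        blocks.append(_Block(name, cols, A_blk, L, prior,
                             _AdaptiveStep(step, tgt, adapt_window), M))

    eye = np.eye
    # scalar fixed effects
    for nm in ("g0", "g1", "delta_sub", "delta_comm", "delta_urb",
               "delta_rural", "delta_urban"):
        add(nm, [sl[nm].start], ("fixed", None), eye(1) / fs2)
    for j in range(layout.n_cov):
        add(f"cov[{layout.config.covariates[j]}]", [sl["cov"].start + j],
            ("fixed", None), eye(1) / fs2)
    # hierarchical deviations (scalar blocks, SD-linked priors)
    for r in range(layout.n_regions):
        add(f"region_int[{r}]", [sl["region_int"].start + r],
            ("hier", "sd_region_int"), eye(1) / sd0 ** 2)
        add(f"region_slope[{r}]", [sl["region_slope"].start + r],
            ("hier", "sd_region_slope"), eye(1) / sd0 ** 2)
    for c in range(layout.n_countries):
        add(f"country_int[{c}]", [sl["country_int"].start + c],
            ("hier", "sd_country_int"), eye(1) / sd0 ** 2)
        add(f"country_slope[{c}]", [sl["country_slope"].start + c],
            ("hier", "sd_country_slope"), eye(1) / sd0 ** 2)
    # per-country RW2 weight vectors
    M = layout.rw2.D2Z
    MtM = M.T @ M
    W = layout.n_rw2
    for c in range(layout.n_countries):
        cols = np.arange(sl["rw2"].start + c * W, sl["rw2"].start + (c + 1) * W)
        add(f"rw2[{c}]", cols, ("rw2", None), MtM / sd0 ** 2, M=M)
    # age coefficients
    K = layout.n_age_basis
    add("age_global", np.arange(sl["age_global"].start, sl["age_global"].stop),
        ("fixed", None), eye(K) / fs2)
    for c in range(layout.n_countries):
        cols = np.arange(sl["age_country"].start + c * K,
                         sl["age_country"].start + (c + 1) * K)
        add(f"age_country[{c}]", cols, ("hier", "sd_age_dev"), eye(K) / sd0 ** 2)
    return blocks


def _initial_coef(data: ModelData) -> np.ndarray:
    """Data-driven least-squares start for the non-hierarchical effects."""
    layout = data.layout
    sl = layout.slices
    cols = [sl["g0"].start, sl["g1"].start,
            sl["delta_sub"].start, sl["delta_comm"].start,
            sl["delta_urb"].start]
    cols += list(range(sl["cov"].start, sl["cov"].stop))
    cols += list(range(sl["age_global"].start, sl["age_global"].stop))
    cols = np.asarray(cols, dtype=int)
    X = data.A[:, cols]
    beta = np.linalg.solve(X.T @ X + 1e-6 * np.eye(len(cols)), X.T @ data.y)
    coef = np.zeros(layout.n_coef)
    coef[cols] = beta
    return coef


def run_chain(data: ModelData, schedule: MCMCSchedule, chain_index: int,
              monitor: Sequence[str] = ()) -> dict:
    """Run one MCMC chain; returns thinned draws and acceptance rates.

    Deterministic given ``(schedule.seed, chain_index)``.
    """
    layout = data.layout
    rng = np.random.default_rng(
        np.random.SeedSequence((int(schedule.seed), int(chain_index))))
    sd0 = 0.1
    sds = np.full(layout.n_sd, sd0)
    coef = _initial_coef(data)
    blocks = _build_blocks(data, tau0=sd0, sd0=sd0, adapt_window=schedule.adapt_window)

    sl = layout.slices
    fs2 = layout.config.prior_fixed_sd ** 2
    prior_scale = layout.config.prior_sd_scale
    sd_index = {nm: i for i, nm in enumerate(SD_NAMES)}
    M = layout.rw2.D2Z
    W = layout.n_rw2
    C = layout.n_countries

    # cached likelihood pieces
    tau = sds[6:9]
    var = data.sampling_var + np.square(tau)[data.coverage_code]
    wv = 1.0 / var
    r = data.y - data.A @ coef
    quad = float(np.dot(r * wv, r))
    if not np.isfinite(quad):
        raise RuntimeError("non-finite log-posterior at initialisation "
                           "(likelihood block)")
    # cached RW2 penalty sums per country
    w_mat = coef[sl["rw2"]].reshape(C, W)
    Mw = w_mat @ M.T
    rw2_ssq = np.einsum("ij,ij->i", Mw, Mw)

    class_rows = [np.flatnonzero(data.coverage_code == k) for k in range(3)]

    def hier_ssq(sd_name: str) -> tuple[float, int]:
        if sd_name == "sd_region_int":
            v = coef[sl["region_int"]]
        elif sd_name == "sd_region_slope":
            v = coef[sl["region_slope"]]
        elif sd_name == "sd_country_int":
            v = coef[sl["country_int"]]
        elif sd_name == "sd_country_slope":
            v = coef[sl["country_slope"]]
        elif sd_name == "sd_age_dev":
            v = coef[sl["age_country"]]
        elif sd_name == "sd_rw2":
            return float(rw2_ssq.sum()), C * (layout.hierarchy.n_years - 2)
        else:  # pragma: no cover
            raise KeyError(sd_name)
        return float(np.dot(v, v)), len(v)

    sd_steppers = {nm: _AdaptiveStep(0.3, 0.44, schedule.adapt_window)
                   for nm in SD_NAMES}

    # ---- extra mixing moves ------------------------------------------------
    # Translation moves shift mass between hierarchy levels along directions
    # that leave the likelihood exactly invariant (a region's intercept
    # column equals the sum of its countries' columns), curing the slow
    # random-walk behaviour of centred hierarchical parameterisations.
    # Scale-interweaving moves rescale a deviation block jointly with its SD
    # (the ancillarity-sufficiency move), which decouples the SD from the
    # amplitude of its deviations.
    translations: list[tuple[str, np.ndarray, np.ndarray, str | None, str | None]] = []

    def _tr(name, src_cols, dst_cols, src_sd, dst_sd):
        translations.append((name, np.asarray(src_cols, int),
                             np.asarray(dst_cols, int), src_sd, dst_sd))

    _tr("t_g0_region", [sl["g0"].start],
        np.arange(sl["region_int"].start, sl["region_int"].stop),
        None, "sd_region_int")
    _tr("t_g1_region", [sl["g1"].start],
        np.arange(sl["region_slope"].start, sl["region_slope"].stop),
        None, "sd_region_slope")
    for r_i, region in enumerate(layout.regions):
        members = np.flatnonzero(layout.country_region == r_i)
        _tr(f"t_region_int[{r_i}]", [sl["region_int"].start + r_i],
            sl["country_int"].start + members, "sd_region_int", "sd_country_int")
        _tr(f"t_region_slope[{r_i}]", [sl["region_slope"].start + r_i],
            sl["country_slope"].start + members, "sd_region_slope",
            "sd_country_slope")
    tr_steppers = {nm: _AdaptiveStep(0.2, 0.44, schedule.adapt_window)
                   for nm, *_ in translations}
    age_tr_stepper = _AdaptiveStep(0.1, 0.30, schedule.adapt_window)
    K = layout.n_age_basis
    age_g_cols = np.arange(sl["age_global"].start, sl["age_global"].stop)
    age_c_start = sl["age_country"].start

    scale_moves = [
        ("s_region_int", "sd_region_int", np.arange(sl["region_int"].start, sl["region_int"].stop)),
        ("s_region_slope", "sd_region_slope", np.arange(sl["region_slope"].start, sl["region_slope"].stop)),
        ("s_country_int", "sd_country_int", np.arange(sl["country_int"].start, sl["country_int"].stop)),
        ("s_country_slope", "sd_country_slope", np.arange(sl["country_slope"].start, sl["country_slope"].stop)),
        ("s_age_dev", "sd_age_dev", np.arange(sl["age_country"].start, sl["age_country"].stop)),
        ("s_rw2", "sd_rw2", np.arange(sl["rw2"].start, sl["rw2"].stop)),
    ]
    scale_A = {nm: np.ascontiguousarray(data.A[:, cols])
               for nm, _, cols in scale_moves}
    scale_steppers = {nm: _AdaptiveStep(0.1, 0.44, schedule.adapt_window)
                      for nm, *_ in scale_moves}

    def refresh_preconditioners() -> None:
        """Rebuild block proposal shapes at the current variance components.

        Called during burn-in only, so the post-burn-in kernel is fixed;
        this lets e.g. RW2 proposals match the current smoothing level
        instead of the initial one.
        """
        sd_of = dict(zip(SD_NAMES, sds))
        for blk in blocks:
            kind, sd_name = blk.prior
            d = len(blk.cols)
            if kind == "fixed":
                prior_prec = np.eye(d) / fs2
            elif kind == "hier":
                prior_prec = np.eye(d) / max(sd_of[sd_name], 1e-6) ** 2
            else:  # rw2
                prior_prec = (M.T @ M) / max(sd_of["sd_rw2"], 1e-6) ** 2
            gram = (blk.A * wv[:, None]).T @ blk.A + prior_prec
            cov = np.linalg.inv(gram)
            blk.L = np.linalg.cholesky(0.5 * (cov + cov.T))

    n_keep = schedule.per_chain_size
    keep = set(thinning_indices(schedule.retained_iterations, n_keep).tolist())
    out = np.empty((n_keep, layout.n_params))
    k_out = 0

    for t in range(schedule.n_iter):
        adapting = t < schedule.burn_in
        if adapting and t > 0 and t % 100 == 0:
            refresh_preconditioners()
        # ---- coefficient blocks ----
        for blk in blocks:
            d = len(blk.cols)
            z = rng.standard_normal(d)
            delta = blk.stepper.scale() * (blk.L @ z)
            dr = blk.A @ delta
            r_prop = r - dr
            quad_prop = float(np.dot(r_prop * wv, r_prop))
            dlp = -0.5 * (quad_prop - quad)
            cur = coef[blk.cols]
            new = cur + delta
            kind, sd_name = blk.prior
            if kind == "fixed":
                dlp += -0.5 * (np.dot(new, new) - np.dot(cur, cur)) / fs2
            elif kind == "hier":
                s2 = sds[sd_index[sd_name]] ** 2
                dlp += -0.5 * (np.dot(new, new) - np.dot(cur, cur)) / s2
            else:  # rw2
                c_idx = int(blk.name[4:-1])
                mw_new = Mw[c_idx] + blk.M @ delta
                ssq_new = float(np.dot(mw_new, mw_new))
                dlp += -0.5 * (ssq_new - rw2_ssq[c_idx]) / sds[sd_index["sd_rw2"]] ** 2
            alpha = float(np.exp(min(dlp, 0.0)))
            if rng.random() < alpha:
                coef[blk.cols] = new
                r, quad = r_prop, quad_prop
                if kind == "rw2":
                    Mw[c_idx] = mw_new
                    rw2_ssq[c_idx] = ssq_new
                blk.stepper.record(True)
            else:
                blk.stepper.record(False)
            blk.stepper.update(alpha, t, adapting)

        # ---- hierarchical SDs (log-scale RWM) ----
        # these updates are O(1) thanks to cached sums of squares, so the
        # sweep is repeated within each iteration to sharpen their mixing
        for _ in range(3):
            for nm in ("sd_region_int", "sd_region_slope", "sd_country_int",
                       "sd_country_slope", "sd_rw2", "sd_age_dev"):
                st = sd_steppers[nm]
                i = sd_index[nm]
                s = sds[i]
                s_prop = float(s * np.exp(st.scale() * rng.standard_normal()))
                ssq, k = hier_ssq(nm)

                def sd_logpost(x: float) -> float:
                    return (-k * np.log(x) - 0.5 * ssq / (x * x)
                            - 0.5 * x * x / (prior_scale ** 2) + np.log(x))

                dlp = sd_logpost(s_prop) - sd_logpost(s)
                alpha = float(np.exp(min(dlp, 0.0)))
                if rng.random() < alpha:
                    sds[i] = s_prop
                    st.record(True)
                else:
                    st.record(False)
                st.update(alpha, t, adapting)

        # ---- coverage-class variance inflations ----
        for k_cls, nm in enumerate(("tau_national", "tau_subnational",
                                    "tau_community")):
            st = sd_steppers[nm]
            i = sd_index[nm]
            rows = class_rows[k_cls]
            s = sds[i]
            s_prop = float(s * np.exp(st.scale() * rng.standard_normal()))
            if len(rows):
                v_new = data.sampling_var[rows] + s_prop * s_prop
                v_old = data.sampling_var[rows] + s * s
                r2 = np.square(r[rows])
                dlik = float(-0.5 * np.sum(np.log(v_new) - np.log(v_old))
                             - 0.5 * np.sum(r2 / v_new - r2 / v_old))
            else:
                dlik = 0.0
            dlp = dlik - 0.5 * (s_prop ** 2 - s ** 2) / prior_scale ** 2 \
                + (np.log(s_prop) - np.log(s))
            alpha = float(np.exp(min(dlp, 0.0)))
            if rng.random() < alpha:
                sds[i] = s_prop
                if len(rows):
                    wv[rows] = 1.0 / v_new
                    quad = float(np.dot(r * wv, r))
                st.record(True)
            else:
                st.record(False)
            st.update(alpha, t, adapting)

        # ---- likelihood-invariant recentering translations ----
        for nm, src, dst, src_sd, dst_sd in translations:
            st = tr_steppers[nm]
            d = st.scale() * rng.standard_normal()
            s_src2 = fs2 if src_sd is None else sds[sd_index[src_sd]] ** 2
            s_dst2 = sds[sd_index[dst_sd]] ** 2
            sv_, dv_ = coef[src], coef[dst]
            dlp = (-0.5 * (np.sum((sv_ + d) ** 2) - np.sum(sv_ ** 2)) / s_src2
                   - 0.5 * (np.sum((dv_ - d) ** 2) - np.sum(dv_ ** 2)) / s_dst2)
            alpha = float(np.exp(min(dlp, 0.0)))
            if rng.random() < alpha:
                coef[src] = sv_ + d
                coef[dst] = dv_ - d
                st.record(True)
            else:
                st.record(False)
            st.update(alpha, t, adapting)

        # global age curve vs country deviations (vector translation)
        dvec = age_tr_stepper.scale() * rng.standard_normal(K)
        ag = coef[age_g_cols]
        ac = coef[sl["age_country"]].reshape(C, K)
        s2_age = sds[sd_index["sd_age_dev"]] ** 2
        dlp = (-0.5 * (np.sum((ag + dvec) ** 2) - np.sum(ag ** 2)) / fs2
               - 0.5 * (np.sum((ac - dvec) ** 2) - np.sum(ac ** 2)) / s2_age)
        alpha = float(np.exp(min(dlp, 0.0)))
        if rng.random() < alpha:
            coef[age_g_cols] = ag + dvec
            coef[sl["age_country"]] = (ac - dvec).ravel()
            age_tr_stepper.record(True)
        else:
            age_tr_stepper.record(False)
        age_tr_stepper.update(alpha, t, adapting)

        # ---- scale interweaving: rescale deviations jointly with their SD ----
        for _ in range(2):
            for nm, sd_name, cols in scale_moves:
                st = scale_steppers[nm]
                i = sd_index[sd_name]
                eps = st.scale() * rng.standard_normal()
                fac = float(np.exp(eps))
                vals = coef[cols]
                dr = scale_A[nm] @ (vals * (fac - 1.0))
                r_prop = r - dr
                quad_prop = float(np.dot(r_prop * wv, r_prop))
                s = sds[i]
                s_prop = s * fac
                dlp = (-0.5 * (quad_prop - quad)
                       - 0.5 * (s_prop ** 2 - s ** 2) / prior_scale ** 2 + eps)
                alpha = float(np.exp(min(dlp, 0.0)))
                if rng.random() < alpha:
                    coef[cols] = vals * fac
                    sds[i] = s_prop
                    r, quad = r_prop, quad_prop
                    if sd_name == "sd_rw2":
                        Mw *= fac
                        rw2_ssq *= fac * fac
                    st.record(True)
                else:
                    st.record(False)
                st.update(alpha, t, adapting)

        if not adapting and (t - schedule.burn_in) in keep:
            out[k_out, :layout.n_coef] = coef
            out[k_out, layout.n_coef:] = sds
            k_out += 1

    acceptance = {blk.name: blk.stepper.rate for blk in blocks}
    acceptance.update({nm: st.rate for nm, st in sd_steppers.items()})
    acceptance.update({nm: st.rate for nm, st in tr_steppers.items()})
    acceptance.update({nm: st.rate for nm, st in scale_steppers.items()})
    acceptance["t_age_global"] = age_tr_stepper.rate
    return {"chain_index": chain_index, "draws": out,
            "acceptance": acceptance, "schedule": schedule}


def combine_and_thin(chain_results: Sequence[dict],
                     final_size: int | None = None,
                     layout=None) -> PosteriorDraws:
    """Concatenate chains in order and evenly thin to the final size."""
    if not chain_results:
        raise ValueError("no chains to combine")
    sched = chain_results[0]["schedule"]
    for res in chain_results[1:]:
        if res["schedule"] != sched:
            raise ValueError("chains were run under different schedules")
    draws = np.concatenate([res["draws"] for res in chain_results])
    chain_ids = np.concatenate([
        np.full(len(res["draws"]), res["chain_index"]) for res in chain_results])
    final = final_size if final_size is not None else sched.final_total
    idx = thinning_indices(len(draws), final)
    names = tuple(flat_param_names(layout)) if layout is not None else \
        tuple(f"p{i}" for i in range(draws.shape[1]))
    acc = {}
    for res in chain_results:
        for k, v in res["acceptance"].items():
            acc.setdefault(k, []).append(v)
    return PosteriorDraws(draws[idx], chain_ids[idx], names, sched,
                          layout=layout, acceptance=acc)


def run_chains(data: ModelData, schedule: MCMCSchedule) -> PosteriorDraws:
    """Run all scheduled chains sequentially and combine them."""
    results = [run_chain(data, schedule, k) for k in range(schedule.n_chains)]
    return combine_and_thin(results, layout=data.layout)


def flat_param_names(layout) -> list[str]:
    """Names of the flat parameter vector entries, in layout order."""
    names: list[str] = []
    sl = layout.slices
    order = sorted(sl, key=lambda k: sl[k].start)
    for key in order:
        size = sl[key].stop - sl[key].start
        if size == 1:
            names.append(key)
        elif key in ("region_int", "region_slope"):
            names.extend(f"{key}[{r}]" for r in layout.regions)
        elif key in ("country_int", "country_slope"):
            names.extend(f"{key}[{c}]" for c in layout.countries)
        elif key == "rw2":
            names.extend(f"rw2[{c},{j}]" for c in layout.countries
                         for j in range(layout.n_rw2))
        elif key == "age_global":
            names.extend(f"age_global[{j}]" for j in range(size))
        elif key == "age_country":
            names.extend(f"age_country[{c},{j}]" for c in layout.countries
                         for j in range(layout.n_age_basis))
        elif key == "cov":
            names.extend(f"cov[{nm}]" for nm in layout.config.covariates)
        else:  # pragma: no cover
            names.extend(f"{key}[{j}]" for j in range(size))
    names.extend(SD_NAMES)
    return names


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def rhat(per_chain: Sequence[np.ndarray]) -> float:
    """Split potential scale reduction factor for one scalar parameter."""
    if len(per_chain) < 2:
        raise ValueError("split R-hat needs at least 2 chains")
    lengths = {len(c) for c in per_chain}
    if min(lengths) < 10:
        raise ValueError("split R-hat needs at least 10 draws per chain")
    n = min(lengths) // 2
    halves = []
    for c in per_chain:
        c = np.asarray(c, dtype=float)
        halves.append(c[:n])
        halves.append(c[len(c) - n:])
    x = np.stack(halves)                       # (2m, n)
    m = x.shape[0]
    chain_means = x.mean(axis=1)
    grand = chain_means.mean()
    B = n / (m - 1) * np.sum((chain_means - grand) ** 2)
    Wv = x.var(axis=1, ddof=1).mean()
    if Wv == 0:
        return 1.0
    var_plus = (n - 1) / n * Wv + B / n
    return float(np.sqrt(var_plus / Wv))


def convergence_summary(chain_results: Sequence[dict], layout,
                        monitor: Sequence[str] | None = None) -> dict[str, float]:
    """Split R-hat for a set of monitored scalar parameters."""
    names = flat_param_names(layout)
    if monitor is None:
        monitor = [n for n in ("g0", "g1", "delta_sub", "delta_comm",
                               "delta_urb", "delta_rural", "delta_urban",
                               *SD_NAMES) if n in names]
    out = {}
    for nm in monitor:
        j = names.index(nm)
        out[nm] = rhat([res["draws"][:, j] for res in chain_results])
    return out
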