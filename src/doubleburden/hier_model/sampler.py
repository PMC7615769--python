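"""MH-within-Gibbs sampler for the hierarchical meta-regression.

All linear effects (intercepts, slopes, RW2 weights, spline coefficients,
offsets, urbanisation coefficient, study effects) have jointly Gaussian full
conditionals and are updated in conjugate blocks — one joint block per level
unit (global, each region, each country) so that correlated components mix
together.  Variance parameters get adaptive random-walk Metropolis updates on
the log-SD scale with target acceptance 0.44 (adaptation runs during burn-in
only, so the retained chain is a valid Markov chain).

The same data and spec (including the seed) always reproduce bit-identical
draws.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.linalg import cholesky, solve_triangular

from .context import ModelContext, prior_segments
from .posterior import log_posterior
from .spec import SD_NAMES, ModelSpec, ParameterState

__all__ = ["ModelFit", "mcmc_fit"]

_TAU_BY_COV = ("tau_national", "tau_subnational", "tau_community")
_TARGET_ACCEPT = 0.44
_ADAPT_BATCH = 50


@dataclass
class ModelFit:
    """Posterior draws (post burn-in, thinned, all chains) for one fit."""

    ctx: ModelContext
    spec: ModelSpec
    theta: np.ndarray             # (chains, n_keep, n_params)
    sds: np.ndarray               # (chains, n_keep, n_sds)
    sd_names: tuple[str, ...]
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0] * self.theta.shape[1]

    def stacked_theta(self) -> np.ndarray:
        return self.theta.reshape(-1, self.theta.shape[-1])

    def sd_draws(self, name: str) -> np.ndarray:
        """Draws of one SD parameter, shape (chains, n_keep)."""
        return self.sds[:, :, self.sd_names.index(name)]

    def param_draws(self, name: str) -> np.ndarray:
        """Stacked draws of one linear parameter group, shape (D, size)."""
        return self.stacked_theta()[:, self.ctx.slices[name]]


def _active_sds(ctx: ModelContext) -> list[str]:
    """SD parameters that govern at least one active group (MH targets)."""
    spec = ctx.spec
    names: list[str] = []
    segs = prior_segments(ctx)
    governed = {seg.sd_name for name in ctx.slices for seg in segs[name]
                if seg.sd_name is not None}
    for cov_i, tau in enumerate(_TAU_BY_COV):
        if ctx.has("e_study") and np.any(ctx.study_cov == cov_i):
            governed.add(tau)
    for name in SD_NAMES:
        if name in governed and not spec.sd_is_fixed(name):
            names.append(name)
    return names


def _governing_sds(ctx: ModelContext) -> dict[str, float]:
    """Initial/required SD values: fixed ones from the spec, others seeded."""
    spec = ctx.spec
    segs = prior_segments(ctx)
    out: dict[str, float] = {}
    for name in ctx.slices:
        for seg in segs[name]:
            if seg.sd_name is not None:
                out[seg.sd_name] = spec.fixed_sd.get(seg.sd_name, 0.3)
    if ctx.has("e_study"):
        for cov_i, tau in enumerate(_TAU_BY_COV):
            if np.any(ctx.study_cov == cov_i):
                out[tau] = spec.fixed_sd.get(tau, 0.3)
    return out


@dataclass
class _Block:
    name: str
    cols: np.ndarray
    x: np.ndarray        # (n_obs, d)
    g: np.ndarray        # X' W X
    xtw: np.ndarray      # X' W
    segments: list       # (local_start, size, kind, sd_name, fixed_value)


def _build_blocks(ctx: ModelContext) -> list[_Block]:
    segs = prior_segments(ctx)
    w = 1.0 / ctx.v if ctx.n_obs else np.zeros(0)
    r, c = len(ctx.regions), len(ctx.countries)
    q = ctx.rw2.dim if ctx.rw2 is not None else 0
    k = ctx.basis.shape[1] if ctx.basis is not None else 0

    def cols_of(name, unit=None, per=0):
        sl = ctx.slices[name]
        if unit is None:
            return np.arange(sl.start, sl.stop)
        return np.arange(sl.start + unit * per, sl.start + (unit + 1) * per)

    specs: list[tuple[str, list]] = []
    global_parts = [(n, None, 0) for n in ("a0", "b0", "w_global", "g_global")
                    if ctx.has(n)]
    specs.append(("global", global_parts))
    for ri in range(r):
        parts = []
        for name, per in (("a_region", 1), ("b_region", 1),
                          ("w_region", q), ("g_region", k)):
            if ctx.has(name):
                parts.append((name, ri, per))
        if parts:
            specs.append((f"region:{ctx.regions[ri]}", parts))
    for ci in range(c):
        parts = []
        for name, per in (("a_country", 1), ("b_country", 1),
                          ("w_country", q), ("g_country", k)):
            if ctx.has(name):
                parts.append((name, ci, per))
        if parts:
            specs.append((f"country:{ctx.countries[ci]}", parts))
    offset_parts = [(n, None, 0) for n in ("delta", "beta_u") if ctx.has(n)]
    if offset_parts:
        specs.append(("offsets", offset_parts))

    blocks = []
    for name, parts in specs:
        if not parts:
            continue
        cols = np.concatenate([cols_of(n, u if p else None, p) for n, u, p in parts])
        x = ctx.design[:, cols] if ctx.n_obs else np.zeros((0, cols.size))
        xtw = x.T * w
        g = xtw @ x
        # seg metadata: iterate parts mirroring cols construction
        seg_meta = []
        offset = 0
        for n, u, p in parts:
            if p:  # per-unit slice of a group
                seg0 = segs[n][0]
                seg_meta.append((offset, p, seg0.kind, seg0.sd_name, seg0.fixed_value))
                offset += p
            else:
                for seg in segs[n]:
                    seg_meta.append((offset + seg.start, seg.size, seg.kind,
                                     seg.sd_name, seg.fixed_value))
                offset += ctx.slices[n].stop - ctx.slices[n].start
        blocks.append(_Block(name=name, cols=cols, x=x, g=g, xtw=xtw,
                             segments=seg_meta))
    return blocks


def _block_prior_precision(block: _Block, sds: Mapping[str, float],
                           ctx: ModelContext) -> np.ndarray:
    d = block.cols.size
    p = np.zeros((d, d))
    for start, size, kind, sd_name, fixed_value in block.segments:
        sd = fixed_value if sd_name is None else sds[sd_name]
        if kind == "iid":
            idx = np.arange(start, start + size)
            p[idx, idx] += 1.0 / sd ** 2
        else:
            p[start:start + size, start:start + size] += ctx.rw2.penalty / sd ** 2
    return p


def _sd_conditional_logdens(name: str, log_sd: float, ctx: ModelContext,
                            theta: np.ndarray, spec: ModelSpec) -> float:
    """log p(log sd | rest): group likelihood + half-normal prior + Jacobian."""
    sd = math.exp(log_sd)
    n_tot, quad = 0, 0.0
    if name in _TAU_BY_COV:
        cov_i = _TAU_BY_COV.index(name)
        e = theta[ctx.slices["e_study"]][ctx.study_cov == cov_i]
        n_tot, quad = e.size, float(e @ e)
    elif name.startswith("sd_rw2"):
        group = {"sd_rw2_global": "w_global", "sd_rw2_region": "w_region",
                 "sd_rw2_country": "w_country"}[name]
        q = ctx.rw2.dim
        w_all = theta[ctx.slices[group]].reshape(-1, q)
        n_tot = w_all.size
        quad = float(np.einsum("ui,ij,uj->", w_all, ctx.rw2.penalty, w_all))
    else:
        group = {"sd_intercept_region": "a_region", "sd_intercept_country": "a_country",
                 "sd_slope_region": "b_region", "sd_slope_country": "b_country",
                 "sd_spline_region": "g_region", "sd_spline_country": "g_country"}[name]
        vec = theta[ctx.slices[group]]
        n_tot, quad = vec.size, float(vec @ vec)
    h = spec.halfnormal_scale.get(name, 1.0)
    return (-n_tot * log_sd - 0.5 * quad / sd ** 2     # group likelihood
            - 0.5 * (sd / h) ** 2                      # half-normal prior
            + log_sd)                                  # Jacobian of log transform


def mcmc_fit(ctx: ModelContext, spec: ModelSpec | None = None) -> ModelFit:
    """Run the MH-within-Gibbs sampler and return retained draws.

    Raises if the burn-in consumes every iteration, and aborts with a state
    dump if any chain's log posterior becomes non-finite (divergence guard).
    Issues a warning for a prior-only fit (no observations).
    """
    spec = spec or ctx.spec
    mc = spec.mcmc
    if mc.n_burn >= mc.iterations:
        raise ValueError("no retained draws: burn-in consumes all iterations")
    if ctx.n_obs == 0:
        warnings.warn("no observations for this category/sex: prior-only fit",
                      stacklevel=2)

    blocks = _build_blocks(ctx)
    sampled_sds = _active_sds(ctx)
    keep_iters = list(range(mc.n_burn, mc.iterations, mc.thin))
    n_keep = len(keep_iters)
    sd_names_all = tuple(sorted(_governing_sds(ctx)))

    theta_out = np.empty((mc.chains, n_keep, ctx.n_params))
    sds_out = np.empty((mc.chains, n_keep, len(sd_names_all)))
    accept_counts = {name: 0 for name in sampled_sds}
    post_burn_updates = 0

    w_obs = 1.0 / ctx.v if ctx.n_obs else np.zeros(0)
    has_e = ctx.has("e_study")
    if has_e:
        e_sl = ctx.slices["e_study"]
        g_study = np.bincount(ctx.obs_study, weights=w_obs, minlength=ctx.n_studies)

    for chain in range(mc.chains):
        rng = np.random.default_rng(np.random.SeedSequence([mc.seed, chain]))
        theta = 0.1 * rng.standard_normal(ctx.n_params)
        sds = _governing_sds(ctx)
        log_steps = {name: math.log(0.5) for name in sampled_sds}
        for name in sampled_sds:
            sds[name] = math.exp(math.log(0.3) + 0.3 * rng.standard_normal())
        batch_accepts = {name: 0 for name in sampled_sds}
        batch_no = 0
        fitted = ctx.design @ theta if ctx.n_obs else np.zeros(0)
        keep_ptr = 0

        for it in range(mc.iterations):
            # --- conjugate Gibbs blocks
            for block in blocks:
                old = theta[block.cols]
                prior_prec = _block_prior_precision(block, sds, ctx)
                a = block.g + prior_prec
                if ctx.n_obs:
                    r_vec = ctx.y - fitted + block.x @ old
                    b = block.xtw @ r_vec
                else:
                    b = np.zeros(block.cols.size)
                lchol = cholesky(a, lower=True)
                mean = solve_triangular(
                    lchol.T, solve_triangular(lchol, b, lower=True), lower=False)
                draw = mean + solve_triangular(
                    lchol.T, rng.standard_normal(block.cols.size), lower=False)
                theta[block.cols] = draw
                if ctx.n_obs:
                    fitted += block.x @ (draw - old)

            # --- study effects (disjoint scalars, vectorised)
            if has_e:
                e = theta[e_sl]
                resid = ctx.y - fitted + e[ctx.obs_study]
                b_s = np.bincount(ctx.obs_study, weights=w_obs * resid,
                                  minlength=ctx.n_studies)
                tau = np.array([sds[_TAU_BY_COV[c]] for c in ctx.study_cov])
                prec = g_study + 1.0 / tau ** 2
                e_new = b_s / prec + rng.standard_normal(ctx.n_studies) / np.sqrt(prec)
                fitted += (e_new - e)[ctx.obs_study]
                theta[e_sl] = e_new

            # --- variance parameters: adaptive log-scale random-walk MH
            for name in sampled_sds:
                ls = math.log(sds[name])
                prop = ls + math.exp(log_steps[name]) * rng.standard_normal()
                prop = min(max(prop, -10.0), 5.0)
                delta = (_sd_conditional_logdens(name, prop, ctx, theta, spec)
                         - _sd_conditional_logdens(name, ls, ctx, theta, spec))
                if math.log(rng.uniform()) < delta:
                    sds[name] = math.exp(prop)
                    batch_accepts[name] += 1
                    if it >= mc.n_burn:
                        accept_counts[name] += 1
            if it >= mc.n_burn:
                post_burn_updates += 1

            # adaptation (burn-in only)
            if it < mc.n_burn and (it + 1) % _ADAPT_BATCH == 0:
                batch_no += 1
                for name in sampled_sds:
                    rate = batch_accepts[name] / _ADAPT_BATCH
                    log_steps[name] += (rate - _TARGET_ACCEPT) / math.sqrt(batch_no)
                    batch_accepts[name] = 0

            # divergence guard
            if (it + 1) % 200 == 0 or it + 1 == mc.iterations:
                if not np.isfinite(theta).all() or (
                        ctx.n_obs and not np.isfinite(fitted).all()):
                    state = ParameterState(theta.copy(), dict(sds))
                    raise RuntimeError(
                        f"divergent chain {chain} at iteration {it}: "
                        f"non-finite state; sds={state.sds}")

            if keep_ptr < n_keep and it == keep_iters[keep_ptr]:
                theta_out[chain, keep_ptr] = theta
                sds_out[chain, keep_ptr] = [sds[n] for n in sd_names_all]
                keep_ptr += 1

        # final sanity check via the full joint density
        lp = log_posterior(ParameterState(theta, dict(sds)), ctx, spec)
        if not np.isfinite(lp):
            raise RuntimeError(f"divergent chain {chain}: log posterior = {lp}")

    acceptance = {
        name: (accept_counts[name] / post_burn_updates if post_burn_updates else 0.0)
        for name in sampled_sds}
    return ModelFit(ctx=ctx, spec=spec, theta=theta_out, sds=sds_out,
                    sd_names=sd_names_all, acceptance=acceptance)
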