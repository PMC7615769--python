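"""Joint log posterior density of the hierarchical meta-regression."""

from __future__ import annotations

import math

import numpy as np

from .context import ModelContext, prior_segments
from .spec import ModelSpec, ParameterState

__all__ = ["log_posterior"]

_LOG2PI = math.log(2.0 * math.pi)


def _logpdf_normal(x: np.ndarray, sd: float) -> float:
    x = np.atleast_1d(x)
    return float(-0.5 * np.sum((x / sd) ** 2) - x.size * (math.log(sd) + 0.5 * _LOG2PI))


def _logpdf_halfnormal(x: float, scale: float) -> float:
    # matches scipy.stats.halfnorm(scale=scale).logpdf
    return 0.5 * math.log(2.0 / math.pi) - math.log(scale) - 0.5 * (x / scale) ** 2


def log_posterior(state: ParameterState, ctx: ModelContext,
                  spec: ModelSpec | None = None) -> float:
    """Sum of the data likelihood, all hierarchical/prior densities, and the
    half-normal densities of the sampled SDs.

    The likelihood is Normal on the logit scale with the delta-method
    variances ``v`` and no additional residual term.  Raises on non-positive
    SDs for active groups.
    """
    spec = spec or ctx.spec
    theta = np.asarray(state.theta, dtype=float)
    if theta.shape != (ctx.n_params,):
        raise ValueError(f"theta has shape {theta.shape}, expected ({ctx.n_params},)")

    for name, sd in state.sds.items():
        if sd <= 0 and spec.fixed_sd.get(name) != 0.0:
            raise ValueError(f"non-positive SD for {name}: {sd}")

    total = 0.0
    # (i) likelihood
    if ctx.n_obs:
        fitted = ctx.design @ theta
        resid = ctx.y - fitted
        total += float(-0.5 * np.sum(resid ** 2 / ctx.v)
                       - 0.5 * np.sum(np.log(ctx.v)) - 0.5 * ctx.n_obs * _LOG2PI)

    # (ii) hierarchical deviations and RW2 increments, (iii) fixed-effect priors
    segs = prior_segments(ctx)
    for name, sl in ctx.slices.items():
        vec = theta[sl]
        if name == "e_study":
            for cov_i, tau_name in enumerate(
                    ("tau_national", "tau_subnational", "tau_community")):
                members = vec[ctx.study_cov == cov_i]
                if members.size:
                    total += _logpdf_normal(members, state.sds[tau_name])
            continue
        for seg in segs[name]:
            part = vec[seg.start:seg.start + seg.size]
            sd = seg.fixed_value if seg.sd_name is None else state.sds[seg.sd_name]
            if seg.kind == "iid":
                total += _logpdf_normal(part, sd)
            else:  # rw2
                m = ctx.rw2.penalty
                quad = float(part @ m @ part)
                _, logdet = np.linalg.slogdet(m)
                total += float(-0.5 * quad / sd ** 2 - seg.size * math.log(sd)
                               + 0.5 * logdet - 0.5 * seg.size * _LOG2PI)

    # half-normal priors on sampled SDs
    for name, sd in state.sds.items():
        if spec.sd_is_fixed(name):
            continue
        total += _logpdf_halfnormal(sd, spec.halfnormal_scale.get(name, 1.0))
    return total
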