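"""National prevalence predictions from parameter draws.

Predictions target the national, representative quantity: no coverage offset,
no study effect, and the urbanisation term at its mixed (zero) level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sampler import ModelFit

__all__ = ["predict_prevalence", "fits_to_draws"]


def predict_prevalence(fit: ModelFit, country: str,
                       years: "np.ndarray | None" = None,
                       age_bands: "list[tuple[float, float]] | None" = None
                       ) -> np.ndarray:
    """Posterior draws of national prevalence, shape (D, n_years, n_bands).

    Per draw, the logit prevalence is assembled from the global + region +
    country intercepts and slopes, the RW2 components at all levels, and the
    hierarchical age spline, then inverse-logit transformed.  Values are
    strictly inside (0, 1).
    """
    ctx = fit.ctx
    if country not in ctx.countries:
        raise KeyError(f"unknown country {country!r}")
    ci = ctx.countries.index(country)
    ri = int(ctx.region_of_country[ci])

    if years is None:
        year_idx = np.arange(len(ctx.years))
    else:
        year_idx = np.array([list(ctx.years).index(int(y)) for y in years])
    if age_bands is None:
        band_idx = np.arange(len(ctx.spec.age_grid))
    else:
        grid = [tuple(map(float, b)) for b in ctx.spec.age_grid]
        band_idx = np.array([grid.index(tuple(map(float, b))) for b in age_bands])

    theta = fit.stacked_theta()
    d = theta.shape[0]
    t = ctx.t_scaled[year_idx]

    def grp(name, unit=None, per=1):
        if not ctx.has(name):
            return 0.0
        sl = ctx.slices[name]
        if unit is None:
            return theta[:, sl]
        return theta[:, sl.start + unit * per: sl.start + (unit + 1) * per]

    level = theta[:, ctx.slices["a0"]].sum(axis=1)
    for name, unit in (("a_region", ri), ("a_country", ci)):
        if ctx.has(name):
            level = level + grp(name, unit)[:, 0]
    slope = np.zeros(d)
    for name, unit in (("b0", None), ("b_region", ri), ("b_country", ci)):
        if ctx.has(name):
            vec = grp(name, unit) if unit is not None else theta[:, ctx.slices["b0"]]
            slope = slope + vec[:, 0]

    time_part = level[:, None] + slope[:, None] * t[None, :]
    if ctx.rw2 is not None:
        z = ctx.rw2.z[year_idx]  # (T, q)
        q = ctx.rw2.dim
        for name, unit in (("w_global", None), ("w_region", ri), ("w_country", ci)):
            if ctx.has(name):
                w = grp(name, unit, q) if unit is not None else theta[:, ctx.slices[name]]
                time_part = time_part + w @ z.T

    if ctx.basis is not None:
        b = ctx.basis[band_idx]  # (A, k)
        k = ctx.basis.shape[1]
        g = theta[:, ctx.slices["g_global"]].copy()
        for name, unit in (("g_region", ri), ("g_country", ci)):
            if ctx.has(name):
                g = g + grp(name, unit, k)
        age_part = g @ b.T  # (D, A)
    else:
        age_part = np.zeros((d, band_idx.size))

    logit = time_part[:, :, None] + age_part[:, None, :]
    return 1.0 / (1.0 + np.exp(-logit))


def fits_to_draws(fits: "dict[tuple[str, str], ModelFit]",
                  countries: "list[str] | None" = None):
    """Assemble per-(category, sex) fits into a single cell-indexed draw set.

    Returns a :class:`~doubleburden.posterior_quantities.PosteriorDraws` with
    cells (country, year, sex, age_lo, age_hi, category) and one column per
    cell.  All fits must share MCMC settings (equal draw counts).
    """
    from ..posterior_quantities import PosteriorDraws

    blocks = []
    frames = []
    for (category, sex), fit in sorted(fits.items()):
        ctx = fit.ctx
        use = countries if countries is not None else ctx.countries
        for country in use:
            arr = predict_prevalence(fit, country)  # (D, T, A)
            d, n_t, n_a = arr.shape
            blocks.append(arr.reshape(d, n_t * n_a))
            grid = list(ctx.spec.age_grid)
            frames.append(pd.DataFrame({
                "country": np.repeat(country, n_t * n_a),
                "year": np.repeat(ctx.years, n_a),
                "sex": sex,
                "age_lo": np.tile([b[0] for b in grid], n_t),
                "age_hi": np.tile([b[1] for b in grid], n_t),
                "category": category,
            }))
    values = np.concatenate(blocks, axis=1)
    cells = pd.concat(frames, ignore_index=True)
    return PosteriorDraws(values=values, cells=cells)
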