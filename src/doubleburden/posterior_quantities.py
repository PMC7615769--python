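"""Derived quantities computed strictly at the posterior-draw level.

Every reported number is a function of the draw array — summaries (means,
2.5th/97.5th percentiles, posterior probabilities) are taken only after the
transformation of interest has been applied per draw, never the other way
round.  Undefined values (0/0 shares, zero-variance correlations) propagate
as NaN "indeterminate" markers and are surfaced, not dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .study_db import AgeStandard

__all__ = [
    "PosteriorDraws",
    "DerivedSummary",
    "CrossoverSummary",
    "summarise",
    "age_standardise",
    "combined_prevalence",
    "obesity_share",
    "posterior_prob_increase",
    "posterior_prob_decrease",
    "posterior_prob_dominance",
    "persons_affected",
    "correlate_across_countries",
    "crossover_year",
]

CELL_COLUMNS = ["country", "year", "sex", "age_lo", "age_hi", "category"]


@dataclass
class PosteriorDraws:
    """Draw-indexed array on the probability (or count) scale.

    ``values`` has shape (D, n_cells); ``cells`` is a DataFrame with one row
    per cell using a documented subset of ``CELL_COLUMNS`` (dimensions may be
    collapsed by operations such as age standardisation).
    """

    values: np.ndarray
    cells: pd.DataFrame

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_draws, n_cells)")
        if self.values.shape[1] != len(self.cells):
            raise ValueError(
                f"{self.values.shape[1]} value columns vs {len(self.cells)} cells")
        self.cells = self.cells.reset_index(drop=True)

    @property
    def n_draws(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def select(self, **criteria) -> "PosteriorDraws":
        """Subset cells by equality on cell columns (e.g. sex="female")."""
        mask = np.ones(len(self.cells), dtype=bool)
        for col, val in criteria.items():
            mask &= (self.cells[col] == val).to_numpy()
        return PosteriorDraws(self.values[:, mask], self.cells.loc[mask])

    def drop_columns(self, *cols: str) -> "PosteriorDraws":
        return PosteriorDraws(self.values, self.cells.drop(columns=list(cols)))

    def summary_frame(self) -> pd.DataFrame:
        """Cells plus mean/lo/hi columns (percentiles of the draws)."""
        out = self.cells.copy()
        out["mean"] = np.nanmean(self.values, axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out["lo"] = np.nanpercentile(self.values, 2.5, axis=0)
            out["hi"] = np.nanpercentile(self.values, 97.5, axis=0)
        return out


@dataclass(frozen=True)
class DerivedSummary:
    """Posterior mean with the 2.5th-97.5th percentile credible interval."""

    mean: float
    lo: float
    hi: float
    prob: Mapping[str, float] = field(default_factory=dict)
    n_indeterminate: int = 0

    def __post_init__(self):
        if np.isfinite([self.mean, self.lo, self.hi]).all():
            if not (self.lo <= self.mean + 1e-12 and self.mean <= self.hi + 1e-12):
                raise ValueError(f"invalid summary: lo={self.lo} mean={self.mean} hi={self.hi}")


def summarise(draws: np.ndarray, **prob) -> DerivedSummary:
    """Mean and type-7 (linear interpolation) 2.5/97.5 percentiles of a
    1-D draw vector; NaN draws are counted as indeterminate and excluded."""
    arr = np.asarray(draws, dtype=float).ravel()
    bad = int(np.isnan(arr).sum())
    ok = arr[~np.isnan(arr)]
    if ok.size == 0:
        return DerivedSummary(float("nan"), float("nan"), float("nan"),
                              prob, n_indeterminate=bad)
    lo, hi = np.percentile(ok, [2.5, 97.5])  # numpy default = type-7 linear
    return DerivedSummary(float(ok.mean()), float(lo), float(hi), prob,
                          n_indeterminate=bad)


def _require_aligned(a: PosteriorDraws, b: PosteriorDraws,
                     ignore: Sequence[str] = ()) -> None:
    if a.n_draws != b.n_draws:
        raise ValueError(f"draw counts differ: {a.n_draws} vs {b.n_draws}")
    ca = a.cells.drop(columns=[c for c in ignore if c in a.cells], errors="ignore")
    cb = b.cells.drop(columns=[c for c in ignore if c in b.cells], errors="ignore")
    if list(ca.columns) != list(cb.columns) or not ca.reset_index(drop=True).equals(
            cb.reset_index(drop=True)):
        raise ValueError("cell indexes are misaligned")


def age_standardise(draws: PosteriorDraws, standard: AgeStandard) -> PosteriorDraws:
    """Collapse the age dimension with the standard's weights, per draw.

    Every age band present must be a band of the standard; weights are
    renormalised over the bands actually covered.  A band absent from the
    standard raises an error naming the uncovered ages.
    """
    cells = draws.cells
    if "age_lo" not in cells or "age_hi" not in cells:
        raise ValueError("draws have no age dimension to standardise")
    std_w = {(float(lo), float(hi)): w for lo, hi, w in standard.bands}
    bands = list(zip(cells["age_lo"].astype(float), cells["age_hi"].astype(float)))
    missing = sorted({b for b in bands if b not in std_w})
    if missing:
        raise ValueError(f"age bands not covered by the standard: {missing}")

    other = [c for c in cells.columns if c not in ("age_lo", "age_hi")]
    weights = np.array([std_w[b] for b in bands])
    groups = cells.groupby(other, sort=True, dropna=False).indices

    out_vals = np.empty((draws.n_draws, len(groups)))
    out_rows = []
    for gi, (key, idx) in enumerate(sorted(groups.items(), key=lambda kv: kv[0])):
        w = weights[idx]
        w = w / w.sum()  # renormalise over covered bands
        out_vals[:, gi] = draws.values[:, idx] @ w
        out_rows.append(key if isinstance(key, tuple) else (key,))
    return PosteriorDraws(out_vals, pd.DataFrame(out_rows, columns=other))


def combined_prevalence(low: PosteriorDraws, obese: PosteriorDraws) -> PosteriorDraws:
    """Per-draw elementwise sum of the two category prevalences (the double
    burden).  Warns if any summed draw exceeds 1."""
    _require_aligned(low, obese, ignore=("category",))
    vals = low.values + obese.values
    if np.any(vals > 1.0 + 1e-9):
        warnings.warn("combined prevalence exceeds 1 in some draws "
                      "(inputs violate the category-sum constraint)", stacklevel=2)
    cells = low.cells.drop(columns=[c for c in ("category",) if c in low.cells])
    return PosteriorDraws(vals, cells)


def obesity_share(low: PosteriorDraws, obese: PosteriorDraws) -> PosteriorDraws:
    """Per-draw share obese / (low + obese); 0/0 propagates as NaN."""
    _require_aligned(low, obese, ignore=("category",))
    denom = low.values + obese.values
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(denom > 0, obese.values / np.where(denom > 0, denom, 1.0),
                         np.nan)
    cells = low.cells.drop(columns=[c for c in ("category",) if c in low.cells])
    return PosteriorDraws(share, cells)


def posterior_prob_increase(at_t1: np.ndarray, at_t0: np.ndarray) -> float:
    """Fraction of draws with value(t1) - value(t0) > 0 (ties count to
    neither direction)."""
    a, b = np.asarray(at_t1, dtype=float), np.asarray(at_t0, dtype=float)
    if a.size == 0:
        raise ValueError("zero draws")
    return float(np.mean((a - b) > 0))


def posterior_prob_decrease(at_t1: np.ndarray, at_t0: np.ndarray) -> float:
    a, b = np.asarray(at_t1, dtype=float), np.asarray(at_t0, dtype=float)
    if a.size == 0:
        raise ValueError("zero draws")
    return float(np.mean((a - b) < 0))


def posterior_prob_dominance(obese: np.ndarray, low: np.ndarray) -> tuple[float, float]:
    """(P(obese > low), P(low > obese)); ties excluded, so the sum is <= 1."""
    a, b = np.asarray(obese, dtype=float), np.asarray(low, dtype=float)
    if a.size == 0:
        raise ValueError("zero draws")
    return float(np.mean(a > b)), float(np.mean(b > a))


def persons_affected(draws: PosteriorDraws, population: pd.DataFrame,
                     group_by: Sequence[str] = ()) -> PosteriorDraws:
    """Per draw, prevalence x persons summed over cells.

    ``population`` must cover every cell (matched on whichever of country /
    year / sex / age band the draws carry); missing cells raise.  With
    ``group_by`` the sum is taken within groups (e.g. per country), otherwise
    a single global total per draw is returned.
    """
    keys = [c for c in ("country", "year", "sex", "age_lo", "age_hi")
            if c in draws.cells.columns]
    pop_keyed = population.groupby(keys, sort=False)["persons"].sum()
    try:
        persons = pop_keyed.loc[
            pd.MultiIndex.from_frame(draws.cells[keys]) if len(keys) > 1
            else draws.cells[keys[0]]].to_numpy(dtype=float)
    except KeyError as err:
        raise KeyError(f"population table missing cell(s): {err}") from None
    weighted = draws.values * persons[None, :]
    if not group_by:
        return PosteriorDraws(weighted.sum(axis=1, keepdims=True),
                              pd.DataFrame({"scope": ["total"]}))
    groups = draws.cells.groupby(list(group_by), sort=True).indices
    out_vals = np.empty((draws.n_draws, len(groups)))
    rows = []
    for gi, (key, idx) in enumerate(sorted(groups.items(), key=lambda kv: kv[0])):
        out_vals[:, gi] = weighted[:, idx].sum(axis=1)
        rows.append(key if isinstance(key, tuple) else (key,))
    return PosteriorDraws(out_vals, pd.DataFrame(rows, columns=list(group_by)))


def correlate_across_countries(x: np.ndarray, y: np.ndarray) -> DerivedSummary:
    """Pearson r across countries, computed within each posterior draw.

    ``x`` and ``y`` are (D, n_countries) with matching country order; needs
    at least 3 countries.  Draws in which either variable has zero variance
    yield NaN and are reported as indeterminate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have identical shape")
    if x.shape[1] < 3:
        raise ValueError("need >= 3 countries for a correlation")
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where((sx > 0) & (sy > 0),
                     (xc * yc).sum(axis=1) / np.where(sx * sy > 0, sx * sy, 1.0),
                     np.nan)
    return summarise(r)


@dataclass(frozen=True)
class CrossoverSummary:
    """When series ``a`` first exceeds series ``b`` on the year grid."""

    median_year: float
    lo_year: float
    hi_year: float
    frac_no_crossing: float
    frac_already_crossed: float
    status: str  # "ok", "no-crossing", or "already-crossed"


def crossover_year(a: np.ndarray, b: np.ndarray, years: Sequence[int]
                   ) -> CrossoverSummary:
    """Per draw, the first grid year with a > b, given a <= b at the start.

    Draws that never cross are excluded from the percentiles and reported via
    ``frac_no_crossing``.  If a > b at the grid start in more than half of the
    draws, the result is the "already-crossed" sentinel.  No sub-year
    interpolation is performed (integer year grid).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    years = np.asarray(years)
    if a.shape != b.shape or a.shape[1] != years.size:
        raise ValueError("a, b and years must share the year grid")
    already = a[:, 0] > b[:, 0]
    if already.mean() > 0.5:
        return CrossoverSummary(float("nan"), float("nan"), float("nan"),
                                0.0, float(already.mean()), "already-crossed")
    eligible = ~already
    exceeds = a[eligible] > b[eligible]
    has_cross = exceeds.any(axis=1)
    first = np.where(has_cross, exceeds.argmax(axis=1), -1)
    crossing_years = years[first[has_cross]]
    n_elig = int(eligible.sum())
    frac_none = float((~has_cross).sum() / max(n_elig, 1))
    if crossing_years.size == 0:
        return CrossoverSummary(float("nan"), float("nan"), float("nan"),
                                1.0, float(already.mean()), "no-crossing")
    lo, med, hi = np.percentile(crossing_years, [2.5, 50, 97.5])
    return CrossoverSummary(float(med), float(lo), float(hi), frac_none,
                            float(already.mean()), "ok")
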