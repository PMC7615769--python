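"""Model context: index maps, spline/RW2 structures, the packed parameter
layout and the dense design matrix for one (category, sex) fit."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ..study_db import COVERAGE_LEVELS, RegionHierarchy, TransformedObs
from .basis import Rw2Structure, build_age_basis, build_rw2, center_basis
from .spec import ModelSpec

__all__ = ["ModelContext", "build_context", "PriorSegment"]

_URBAN_CODE = {"urban": 1.0, "rural": -1.0, "mixed": 0.0}


@dataclass(frozen=True)
class PriorSegment:
    """Prior structure of a contiguous run of parameters within a block.

    ``kind`` is "iid" (diagonal precision 1/sd^2) or "rw2" (precision M/sd^2);
    ``sd_name`` names the governing variance parameter, or None when the prior
    SD is a fixed hyperparameter (stored in ``fixed_value``).
    """

    start: int
    size: int
    kind: str
    sd_name: str | None
    fixed_value: float = 0.0


@dataclass
class ModelContext:
    """Likelihood-ready data plus all precomputed structure for one fit."""

    spec: ModelSpec
    category: str
    sex: str
    hierarchy: RegionHierarchy
    countries: list[str]
    regions: list[str]
    region_of_country: np.ndarray  # (C,) region index per country
    years: np.ndarray
    t_scaled: np.ndarray
    rw2: Rw2Structure | None
    basis_raw: np.ndarray | None   # (A, k), partition of unity
    basis: np.ndarray | None       # centered
    # observation vectors
    y: np.ndarray
    v: np.ndarray
    study_ids: list[str]
    study_cov: np.ndarray          # (S,) coverage index per study
    obs_study: np.ndarray
    obs_country: np.ndarray
    obs_region: np.ndarray
    obs_year: np.ndarray           # index into years
    obs_band: np.ndarray
    obs_cov: np.ndarray
    obs_urban: np.ndarray
    # packed layout
    slices: dict[str, slice] = field(default_factory=dict)
    n_params: int = 0
    design: np.ndarray | None = None  # (n_obs, n_params)

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_studies(self) -> int:
        return len(self.study_ids)

    def has(self, name: str) -> bool:
        return name in self.slices

    def unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Split a packed parameter vector into named pieces (2-D for
        per-region / per-country groups)."""
        out = {}
        r, c = len(self.regions), len(self.countries)
        for name, sl in self.slices.items():
            vec = np.asarray(theta[sl])
            if name.endswith("_region") and vec.size % max(r, 1) == 0 and vec.size > r:
                vec = vec.reshape(r, -1)
            elif name.endswith("_country") and name != "b_country" and \
                    vec.size % max(c, 1) == 0 and vec.size > c:
                vec = vec.reshape(c, -1)
            out[name] = vec
        return out


def _group_active(spec: ModelSpec, sd_name: str) -> bool:
    """A deviation group is dropped entirely when its SD is fixed at zero."""
    return spec.fixed_sd.get(sd_name, None) != 0.0


def build_context(observations: Sequence[TransformedObs], hierarchy: RegionHierarchy,
                  spec: ModelSpec, category: str, sex: str) -> ModelContext:
    """Assemble the context for one (category, sex) fit.

    Observations are filtered to the requested category and sex; their years
    and age bands must lie on the spec's grids.
    """
    obs = [o for o in observations if o.category == category and o.sex == sex]
    countries = hierarchy.countries
    regions = hierarchy.regions
    region_index = {r: i for i, r in enumerate(regions)}
    country_index = {c: i for i, c in enumerate(countries)}
    region_of_country = np.array(
        [region_index[hierarchy.region_of(c)] for c in countries])

    years = np.arange(spec.years[0], spec.years[1] + 1)
    mid = 0.5 * (years[0] + years[-1])
    half = 0.5 * (years[-1] - years[0])
    t_scaled = (years - mid) / (half if half > 0 else 1.0)

    band_index = {tuple(map(float, b)): i for i, b in enumerate(spec.age_grid)}

    n = len(obs)
    y = np.empty(n)
    v = np.empty(n)
    obs_country = np.empty(n, dtype=int)
    obs_region = np.empty(n, dtype=int)
    obs_year = np.empty(n, dtype=int)
    obs_band = np.empty(n, dtype=int)
    obs_cov = np.empty(n, dtype=int)
    obs_urban = np.empty(n)
    study_of: dict[str, int] = {}
    study_cov_list: list[int] = []
    obs_study = np.empty(n, dtype=int)

    for i, o in enumerate(obs):
        if o.country not in country_index:
            raise KeyError(f"country {o.country!r} not in hierarchy")
        if not (spec.years[0] <= o.mid_year <= spec.years[1]):
            raise ValueError(f"study {o.study_id}: mid_year {o.mid_year} outside "
                             f"the analysis window {spec.years}")
        key = (float(o.age_lo), float(o.age_hi))
        if key not in band_index:
            raise ValueError(f"study {o.study_id}: age band {key} not on the age grid")
        if o.v <= 0:
            raise ValueError(f"study {o.study_id}: non-positive sampling variance")
        y[i] = o.y
        v[i] = o.v
        obs_country[i] = country_index[o.country]
        obs_region[i] = region_of_country[obs_country[i]]
        obs_year[i] = o.mid_year - spec.years[0]
        obs_band[i] = band_index[key]
        obs_cov[i] = COVERAGE_LEVELS.index(o.coverage)
        obs_urban[i] = _URBAN_CODE[o.urbanisation]
        if o.study_id not in study_of:
            study_of[o.study_id] = len(study_of)
            study_cov_list.append(obs_cov[i])
        obs_study[i] = study_of[o.study_id]

    rw2 = build_rw2(len(years)) if spec.include_rw2 else None
    basis_raw = basis = None
    if spec.include_spline:
        mids = np.array([0.5 * (lo + hi) for lo, hi in spec.age_grid])
        basis_raw = build_age_basis(mids, list(spec.knots))
        row_sums = basis_raw.sum(axis=1)
        assert np.allclose(row_sums, 1.0, atol=1e-10), "basis must be a partition of unity"
        basis = center_basis(basis_raw)

    ctx = ModelContext(
        spec=spec, category=category, sex=sex, hierarchy=hierarchy,
        countries=countries, regions=regions, region_of_country=region_of_country,
        years=years, t_scaled=t_scaled, rw2=rw2, basis_raw=basis_raw, basis=basis,
        y=y, v=v, study_ids=sorted(study_of, key=study_of.get),
        study_cov=np.array(study_cov_list, dtype=int),
        obs_study=obs_study, obs_country=obs_country, obs_region=obs_region,
        obs_year=obs_year, obs_band=obs_band, obs_cov=obs_cov, obs_urban=obs_urban,
    )
    _build_layout_and_design(ctx)
    return ctx


def _build_layout_and_design(ctx: ModelContext) -> None:
    spec = ctx.spec
    r, c = len(ctx.regions), len(ctx.countries)
    q = ctx.rw2.dim if ctx.rw2 is not None else 0
    k = ctx.basis.shape[1] if ctx.basis is not None else 0
    s = ctx.n_studies

    entries: list[tuple[str, int]] = [("a0", 1)]
    if spec.include_slope:
        entries.append(("b0", 1))
    if _group_active(spec, "sd_intercept_region"):
        entries.append(("a_region", r))
    if spec.include_slope and _group_active(spec, "sd_slope_region"):
        entries.append(("b_region", r))
    if _group_active(spec, "sd_intercept_country"):
        entries.append(("a_country", c))
    if spec.include_slope and _group_active(spec, "sd_slope_country"):
        entries.append(("b_country", c))
    if ctx.rw2 is not None:
        if _group_active(spec, "sd_rw2_global"):
            entries.append(("w_global", q))
        if _group_active(spec, "sd_rw2_region"):
            entries.append(("w_region", r * q))
        if _group_active(spec, "sd_rw2_country"):
            entries.append(("w_country", c * q))
    if ctx.basis is not None:
        entries.append(("g_global", k))
        if _group_active(spec, "sd_spline_region"):
            entries.append(("g_region", r * k))
        if _group_active(spec, "sd_spline_country"):
            entries.append(("g_country", c * k))
    if spec.include_offsets:
        entries.append(("delta", 2))  # subnational, community
    if spec.include_urban:
        entries.append(("beta_u", 1))
    if spec.include_study_effects and s > 0:
        entries.append(("e_study", s))

    slices: dict[str, slice] = {}
    pos = 0
    for name, size in entries:
        slices[name] = slice(pos, pos + size)
        pos += size
    ctx.slices = slices
    ctx.n_params = pos

    n = ctx.n_obs
    x = np.zeros((n, pos))
    rows = np.arange(n)
    t_obs = ctx.t_scaled[ctx.obs_year]
    z_obs = ctx.rw2.z[ctx.obs_year] if ctx.rw2 is not None else None
    b_obs = ctx.basis[ctx.obs_band] if ctx.basis is not None else None

    def put(name, cols, values):
        if name in slices:
            x[rows, slices[name].start + cols] = values

    x[:, slices["a0"].start] = 1.0
    if "b0" in slices:
        x[:, slices["b0"].start] = t_obs
    put("a_region", ctx.obs_region, 1.0)
    if "b_region" in slices:
        put("b_region", ctx.obs_region, t_obs)
    put("a_country", ctx.obs_country, 1.0)
    if "b_country" in slices:
        put("b_country", ctx.obs_country, t_obs)
    if z_obs is not None:
        q_ = ctx.rw2.dim
        if "w_global" in slices:
            x[:, slices["w_global"]] = z_obs
        if "w_region" in slices:
            base = slices["w_region"].start
            for j in range(q_):
                x[rows, base + ctx.obs_region * q_ + j] = z_obs[:, j]
        if "w_country" in slices:
            base = slices["w_country"].start
            for j in range(q_):
                x[rows, base + ctx.obs_country * q_ + j] = z_obs[:, j]
    if b_obs is not None:
        k_ = ctx.basis.shape[1]
        x[:, slices["g_global"]] = b_obs
        if "g_region" in slices:
            base = slices["g_region"].start
            for j in range(k_):
                x[rows, base + ctx.obs_region * k_ + j] = b_obs[:, j]
        if "g_country" in slices:
            base = slices["g_country"].start
            for j in range(k_):
                x[rows, base + ctx.obs_country * k_ + j] = b_obs[:, j]
    if "delta" in slices:
        x[:, slices["delta"].start] = (ctx.obs_cov == 1).astype(float)
        x[:, slices["delta"].start + 1] = (ctx.obs_cov == 2).astype(float)
    if "beta_u" in slices:
        x[:, slices["beta_u"].start] = ctx.obs_urban
    if "e_study" in slices:
        x[rows, slices["e_study"].start + ctx.obs_study] = 1.0

    ctx.design = x


def prior_segments(ctx: ModelContext) -> dict[str, list[PriorSegment]]:
    """Prior structure per parameter group, relative to the group's slice."""
    spec = ctx.spec
    q = ctx.rw2.dim if ctx.rw2 is not None else 0
    k = ctx.basis.shape[1] if ctx.basis is not None else 0
    out: dict[str, list[PriorSegment]] = {}
    for name, sl in ctx.slices.items():
        size = sl.stop - sl.start
        if name in ("a0", "b0"):
            segs = [PriorSegment(0, 1, "iid", None, spec.prior_sd["fixed"])]
        elif name == "g_global":
            segs = [PriorSegment(0, size, "iid", None, spec.prior_sd["spline_global"])]
        elif name == "delta":
            segs = [PriorSegment(0, size, "iid", None, spec.prior_sd["offset"])]
        elif name == "beta_u":
            segs = [PriorSegment(0, 1, "iid", None, spec.prior_sd["urban"])]
        elif name == "a_region":
            segs = [PriorSegment(0, size, "iid", "sd_intercept_region")]
        elif name == "b_region":
            segs = [PriorSegment(0, size, "iid", "sd_slope_region")]
        elif name == "a_country":
            segs = [PriorSegment(0, size, "iid", "sd_intercept_country")]
        elif name == "b_country":
            segs = [PriorSegment(0, size, "iid", "sd_slope_country")]
        elif name == "w_global":
            segs = [PriorSegment(0, q, "rw2", "sd_rw2_global")]
        elif name == "w_region":
            segs = [PriorSegment(u * q, q, "rw2", "sd_rw2_region") for u in range(size // q)]
        elif name == "w_country":
            segs = [PriorSegment(u * q, q, "rw2", "sd_rw2_country") for u in range(size // q)]
        elif name == "g_region":
            segs = [PriorSegment(0, size, "iid", "sd_spline_region")]
        elif name == "g_country":
            segs = [PriorSegment(0, size, "iid", "sd_spline_country")]
        elif name == "e_study":
            segs = []  # handled specially (per-study coverage-class variances)
        else:  # pragma: no cover
            raise AssertionError(name)
        out[name] = segs
    return out
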