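"""Synthetic study databases with the statistical structure the model assumes.

Latent country surfaces are built from exactly the fitted model's components
(hierarchical intercepts and slopes, constrained RW2 non-linear trends, and a
hierarchical cubic-spline age pattern), then observed through a survey design
with coverage-level offsets, urbanisation effects, study-level random effects,
and binomial sampling noise.  Every downstream stage is testable against the
stored ground truth without any download.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hier_model.basis import build_age_basis, build_rw2, center_basis
from .study_db import (
    CATEGORIES,
    AgeStandard,
    RegionHierarchy,
    StudyObservation,
    adult_age_grid,
    write_age_standard,
    write_hierarchy,
    write_population,
    write_study_table,
)

__all__ = [
    "SurfaceConfig",
    "DesignConfig",
    "TrueSurface",
    "sample_true_surface",
    "simulate_studies",
    "make_fixture",
    "SCENARIOS",
    "global_crossover_year",
]

_LEVELS = ("global", "region", "country")


def _stream(seed: int, label: str) -> np.random.Generator:
    """Named substream of a master seed (D7): adding new streams or scenarios
    never perturbs existing ones because each label hashes independently."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(label.encode())]))


@dataclass(frozen=True)
class SurfaceConfig:
    """Shape and effect scales of the latent prevalence surface."""

    regions: int = 3
    countries_per_region: int = 4
    years: tuple[int, int] = (1990, 2010)
    age_grid: tuple[tuple[float, float], ...] = tuple(adult_age_grid())
    sexes: tuple[str, ...] = ("female", "male")
    baselines: Mapping[str, float] = field(
        default_factory=lambda: {"low": -1.8, "obese": -2.0})
    trends: Mapping[str, float] = field(
        default_factory=lambda: {"low": -0.5, "obese": 0.7})
    intercept_scale: Mapping[str, float] = field(
        default_factory=lambda: {"region": 0.3, "country": 0.2})
    slope_scale: Mapping[str, float] = field(
        default_factory=lambda: {"region": 0.15, "country": 0.1})
    rw2_scale: Mapping[str, float] = field(
        default_factory=lambda: {"global": 0.1, "region": 0.05, "country": 0.05})
    spline_scale: Mapping[str, float] = field(
        default_factory=lambda: {"global": 0.3, "region": 0.1, "country": 0.05})
    knots: tuple[float, ...] = (35.0, 50.0, 65.0)

    def __post_init__(self):
        for m in (self.intercept_scale, self.slope_scale, self.rw2_scale, self.spline_scale):
            if any(v < 0 for v in m.values()):
                raise ValueError("effect scales must be >= 0")
        if self.regions < 1 or self.countries_per_region < 1:
            raise ValueError("need at least one region and one country")
        if self.years[1] < self.years[0]:
            raise ValueError("degenerate year range")

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1

    def country_names(self) -> list[str]:
        return [f"C{i:02d}" for i in range(self.regions * self.countries_per_region)]

    def region_names(self) -> list[str]:
        return [f"R{i}" for i in range(self.regions)]

    def hierarchy(self) -> RegionHierarchy:
        mapping = {}
        for i, c in enumerate(self.country_names()):
            mapping[c] = self.region_names()[i // self.countries_per_region]
        return RegionHierarchy(mapping)


@dataclass(frozen=True)
class DesignConfig:
    """Survey design: how studies observe the latent surface."""

    studies_per_country: "int | Mapping[str, int]" = 8
    coverage_mix: tuple[float, float, float] = (0.375, 0.25, 0.375)  # nat, sub, comm
    urbanisation_mix: tuple[float, float, float] = (0.3, 0.3, 0.4)  # urban, rural, mixed
    sample_size_range: tuple[int, int] = (400, 2000)
    coverage_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"subnational": 0.2, "community": -0.3})
    study_effect_sd: Mapping[str, float] = field(
        default_factory=lambda: {"national": 0.05, "subnational": 0.1, "community": 0.15})
    urban_effect: float = 0.15
    exact: bool = False
    heavy_tailed: bool = False  # misspecification toggle, off by default

    def __post_init__(self):
        if abs(sum(self.coverage_mix) - 1) > 1e-9:
            raise ValueError("coverage mix must sum to 1")
        if abs(sum(self.urbanisation_mix) - 1) > 1e-9:
            raise ValueError("urbanisation mix must sum to 1")
        if any(v < 0 for v in self.study_effect_sd.values()):
            raise ValueError("study-effect SDs must be >= 0")

    def n_studies(self, country: str) -> int:
        if isinstance(self.studies_per_country, int):
            return self.studies_per_country
        return int(self.studies_per_country.get(country, 0))


@dataclass(frozen=True)
class TrueSurface:
    """Latent prevalence with the generating parameters (recovery truth).

    ``prevalence`` has shape (country, year, sex, age band, category) on the
    probability scale; ``params[(category, sex)]`` holds the generating
    hierarchical effects.
    """

    config: SurfaceConfig
    prevalence: np.ndarray
    logit: np.ndarray
    params: Mapping[tuple[str, str], Mapping[str, np.ndarray]]

    @property
    def countries(self) -> list[str]:
        return self.config.country_names()

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.config.years[0], self.config.years[1] + 1)

    def hierarchy(self) -> RegionHierarchy:
        return self.config.hierarchy()

    def cell(self, country: str, year: int, sex: str, band: tuple[float, float],
             category: str) -> float:
        cfg = self.config
        ci = self.countries.index(country)
        ti = int(year) - cfg.years[0]
        si = cfg.sexes.index(sex)
        ai = list(cfg.age_grid).index(tuple(band))
        ki = CATEGORIES.index(category)
        return float(self.prevalence[ci, ti, si, ai, ki])

    def to_frame(self) -> pd.DataFrame:
        """Tidy truth table with the same schema as the estimates output."""
        cfg = self.config
        rows = []
        for ci, country in enumerate(self.countries):
            for ti, year in enumerate(self.years):
                for si, sex in enumerate(cfg.sexes):
                    for ai, (lo, hi) in enumerate(cfg.age_grid):
                        for ki, cat in enumerate(CATEGORIES):
                            rows.append((country, int(year), sex, lo, hi, cat,
                                         self.prevalence[ci, ti, si, ai, ki]))
        return pd.DataFrame(rows, columns=[
            "country", "year", "sex", "age_lo", "age_hi", "category", "prevalence"])


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-x))


def sample_true_surface(config: SurfaceConfig, seed: int) -> TrueSurface:
    """Draw a latent surface from the hierarchical generative model.

    The same (config, seed) always yields the identical surface.  Raises for
    year ranges shorter than 3 years (RW2 undefined).
    """
    n_t = config.n_years
    if n_t < 3:
        raise ValueError("year range must span >= 3 years (RW2 undefined)")
    rw2 = build_rw2(n_t)
    mids = np.array([0.5 * (lo + hi) for lo, hi in config.age_grid])
    basis = center_basis(build_age_basis(mids, list(config.knots)))
    k = basis.shape[1]

    years = np.arange(config.years[0], config.years[1] + 1, dtype=float)
    t_scaled = _scale_years(years)

    countries = config.country_names()
    region_names = config.region_names()
    region_idx = np.repeat(np.arange(config.regions), config.countries_per_region)

    n_c, n_s = len(countries), len(config.sexes)
    n_a = len(config.age_grid)
    logit = np.zeros((n_c, n_t, n_s, n_a, len(CATEGORIES)))
    params: dict[tuple[str, str], dict[str, np.ndarray]] = {}

    for ki, cat in enumerate(CATEGORIES):
        for si, sex in enumerate(config.sexes):
            rng = _stream(seed, f"surface/{cat}/{sex}")
            p = {
                "a_region": rng.normal(0, config.intercept_scale["region"], config.regions),
                "b_region": rng.normal(0, config.slope_scale["region"], config.regions),
                "a_country": rng.normal(0, config.intercept_scale["country"], n_c),
                "b_country": rng.normal(0, config.slope_scale["country"], n_c),
                "w_global": rw2.sample_w(config.rw2_scale["global"], rng),
                "w_region": np.stack([rw2.sample_w(config.rw2_scale["region"], rng)
                                      for _ in range(config.regions)]),
                "w_country": np.stack([rw2.sample_w(config.rw2_scale["country"], rng)
                                       for _ in range(n_c)]),
                "g_global": rng.normal(0, config.spline_scale["global"], k),
                "g_region": rng.normal(0, config.spline_scale["region"], (config.regions, k)),
                "g_country": rng.normal(0, config.spline_scale["country"], (n_c, k)),
            }
            params[(cat, sex)] = p
            u_global = rw2.curve(p["w_global"])
            for ci in range(n_c):
                ri = region_idx[ci]
                trend = (config.baselines[cat]
                         + (config.trends[cat] + p["b_region"][ri] + p["b_country"][ci]) * t_scaled
                         + p["a_region"][ri] + p["a_country"][ci]
                         + u_global + rw2.curve(p["w_region"][ri]) + rw2.curve(p["w_country"][ci]))
                age_curve = basis @ (p["g_global"] + p["g_region"][ri] + p["g_country"][ci])
                logit[ci, :, si, :, ki] = trend[:, None] + age_curve[None, :]

    prevalence = _invlogit(logit)
    return TrueSurface(config=config, prevalence=prevalence, logit=logit, params=params)


def _scale_years(years: np.ndarray) -> np.ndarray:
    mid = 0.5 * (years[0] + years[-1])
    half = 0.5 * (years[-1] - years[0])
    return (years - mid) / (half if half > 0 else 1.0)


def _largest_remainder(proportions: Sequence[float], n: int) -> list[int]:
    raw = [p * n for p in proportions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([-(r - np.floor(r)) for r in raw], kind="stable")
    for j in range(rem):
        counts[order[j]] += 1
    return counts


def simulate_studies(surface: TrueSurface, design: DesignConfig,
                     seed: int) -> list[StudyObservation]:
    """Observe the surface through the survey design.

    Each study draws a coverage class, urbanisation scope, mid-year and
    sample size; its observed logit prevalence is the truth plus the coverage
    offset, the urbanisation effect, and a study-level random effect; counts
    are then drawn multinomially (so prev[low] + prev[obese] <= 1 holds by
    construction).  With ``design.exact`` all offsets, effects and sampling
    noise are disabled and the observed prevalence equals the surface.
    """
    cfg = surface.config
    years = surface.years
    obs: list[StudyObservation] = []
    u_code = {"urban": 1.0, "rural": -1.0, "mixed": 0.0}

    for country in surface.countries:
        n_st = design.n_studies(country)
        if n_st == 0:
            continue
        rng = _stream(seed, f"design/{country}")
        cov_counts = _largest_remainder(design.coverage_mix, n_st)
        coverages = (["national"] * cov_counts[0] + ["subnational"] * cov_counts[1]
                     + ["community"] * cov_counts[2])
        for j, coverage in enumerate(coverages):
            study_id = f"{country}-S{j:02d}"
            mid_year = int(rng.integers(years[0], years[-1] + 1))
            n_sample = int(rng.integers(design.sample_size_range[0],
                                        design.sample_size_range[1] + 1))
            if coverage == "national":
                urbanisation = "mixed"
            else:
                urbanisation = ["urban", "rural", "mixed"][
                    int(rng.choice(3, p=design.urbanisation_mix))]
            offset = design.coverage_offsets.get(coverage, 0.0)
            sd = design.study_effect_sd[coverage]
            if design.heavy_tailed:
                e_study = {cat: sd * rng.standard_t(4) for cat in CATEGORIES}
            else:
                e_study = {cat: rng.normal(0, sd) for cat in CATEGORIES}
            for sex in cfg.sexes:
                for band in cfg.age_grid:
                    if design.exact:
                        prev = {cat: surface.cell(country, mid_year, sex, band, cat)
                                for cat in CATEGORIES}
                    else:
                        shift = offset + design.urban_effect * u_code[urbanisation]
                        p = {}
                        for cat in CATEGORIES:
                            lg = (np.log(surface.cell(country, mid_year, sex, band, cat)
                                         / (1 - surface.cell(country, mid_year, sex, band, cat)))
                                  + shift + e_study[cat])
                            p[cat] = float(_invlogit(lg))
                        total = p["low"] + p["obese"]
                        if total >= 0.999:  # guard; should not trigger for sane configs
                            p = {c: v * 0.999 / total for c, v in p.items()}
                        counts = rng.multinomial(
                            n_sample, [p["low"], p["obese"], 1 - p["low"] - p["obese"]])
                        prev = {"low": counts[0] / n_sample, "obese": counts[1] / n_sample}
                    obs.append(StudyObservation(
                        study_id=study_id, country=country, mid_year=mid_year,
                        sex=sex, age_lo=band[0], age_hi=band[1],
                        coverage=coverage, urbanisation=urbanisation,
                        n_sample=n_sample, prev=prev,
                    ))
    return obs


# ---------------------------------------------------------------------------
# Fixture scenarios


def default_age_standard(age_grid=None) -> AgeStandard:
    """A fixed, mildly decreasing standard over the adult grid (synthetic
    stand-in for a standard population's age weights)."""
    grid = list(age_grid) if age_grid is not None else adult_age_grid()
    raw = np.linspace(1.5, 0.5, len(grid))
    w = raw / raw.sum()
    return AgeStandard(tuple((lo, hi, float(wi)) for (lo, hi), wi in zip(grid, w)))


def _population_frame(surface: TrueSurface, persons_per_band: float = 100_000.0
                      ) -> pd.DataFrame:
    cfg = surface.config
    rows = []
    for country in surface.countries:
        for year in surface.years:
            for sex in cfg.sexes:
                for lo, hi in cfg.age_grid:
                    rows.append((country, int(year), sex, lo, hi, persons_per_band))
    return pd.DataFrame(rows, columns=["country", "year", "sex", "age_lo", "age_hi", "persons"])


def global_crossover_year(surface: TrueSurface, standard: AgeStandard,
                          sex: str) -> "int | None":
    """Brute-force: first year the equal-population global age-standardised
    obesity prevalence exceeds that of the low category."""
    cfg = surface.config
    w = np.array([standard.weight_of(lo, hi) for lo, hi in cfg.age_grid])
    w = w / w.sum()
    si = cfg.sexes.index(sex)
    low = (surface.prevalence[:, :, si, :, CATEGORIES.index("low")] @ w).mean(axis=0)
    ob = (surface.prevalence[:, :, si, :, CATEGORIES.index("obese")] @ w).mean(axis=0)
    if ob[0] > low[0]:
        return None  # already crossed at grid start
    crossed = np.nonzero(ob > low)[0]
    return int(surface.years[crossed[0]]) if crossed.size else None


def _scenario_smoke(seed: int):
    cfg = SurfaceConfig(regions=2, countries_per_region=2, years=(1995, 2005),
                        sexes=("female",))
    design = DesignConfig(studies_per_country=3)
    return cfg, design


def _scenario_shrinkage(seed: int):
    cfg = SurfaceConfig(regions=2, countries_per_region=4, sexes=("female",))
    countries = cfg.country_names()
    per_country = {c: 10 for c in countries}
    per_country[countries[0]] = 0  # zero-data country for the borrowing test
    design = DesignConfig(studies_per_country=per_country)
    return cfg, design


def _scenario_recovery(seed: int):
    cfg = SurfaceConfig()  # desk-scale default: 3 regions x 4 countries x 21 years
    design = DesignConfig(studies_per_country=8)
    return cfg, design


def _scenario_crossover(seed: int):
    cfg = SurfaceConfig(
        sexes=("female",),
        baselines={"low": -1.3, "obese": -1.45},
        trends={"low": -0.55, "obese": 0.75},
        intercept_scale={"region": 0.15, "country": 0.1},
        slope_scale={"region": 0.08, "country": 0.05},
        rw2_scale={"global": 0.05, "region": 0.03, "country": 0.03},
        spline_scale={"global": 0.2, "region": 0.05, "country": 0.03},
    )
    design = DesignConfig(studies_per_country=8)
    return cfg, design


SCENARIOS = {
    "smoke": _scenario_smoke,
    "shrinkage": _scenario_shrinkage,
    "crossover": _scenario_crossover,
    "recovery": _scenario_recovery,
}


def make_fixture(scenario: str, seed: int, out_dir: "str | Path") -> dict[str, Path]:
    """Write a complete synthetic file set for a named scenario.

    Produces studies.csv, hierarchy.csv, age_standard.csv, population.csv,
    truth_surface.csv and truth_meta.json (generating design parameters and,
    for the crossover scenario, the embedded global crossover year).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg, design = SCENARIOS[scenario](seed)
    surface = sample_true_surface(cfg, seed)
    # generated surfaces must satisfy the category-sum constraint everywhere
    sums = surface.prevalence.sum(axis=-1)
    if not (sums <= 1.0).all():
        raise AssertionError("fixture surface violates prev[low] + prev[obese] <= 1")
    studies = simulate_studies(surface, design, seed)
    hierarchy = cfg.hierarchy()
    standard = default_age_standard(cfg.age_grid)

    paths = {
        "studies": out / "studies.csv",
        "hierarchy": out / "hierarchy.csv",
        "age_standard": out / "age_standard.csv",
        "population": out / "population.csv",
        "truth_surface": out / "truth_surface.csv",
        "truth_meta": out / "truth_meta.json",
    }
    write_study_table(studies, paths["studies"], region_of=hierarchy.region_of)
    write_hierarchy(hierarchy, paths["hierarchy"])
    write_age_standard(standard, paths["age_standard"])
    write_population(_population_frame(surface), paths["population"])
    surface.to_frame().to_csv(paths["truth_surface"], index=False)

    meta = {
        "scenario": scenario,
        "seed": seed,
        "years": list(cfg.years),
        "sexes": list(cfg.sexes),
        "knots": list(cfg.knots),
        "coverage_offsets": dict(design.coverage_offsets),
        "urban_effect": design.urban_effect,
        "study_effect_sd": dict(design.study_effect_sd),
        "n_studies": len({o.study_id for o in studies}),
    }
    if scenario == "crossover":
        meta["crossover_year"] = {
            sex: global_crossover_year(surface, standard, sex) for sex in cfg.sexes}
    with paths["truth_meta"].open("w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return paths
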