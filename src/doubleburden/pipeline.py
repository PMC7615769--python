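"""End-to-end orchestration: simulate -> fit -> summarise -> classify ->
report, with YAML configuration and per-stage timing logs."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import posterior_quantities as pq
from . import report as rpt
from .hier_model import (
    ModelSpec,
    convergence_diagnostics,
    fit_studies,
    fits_to_draws,
)
from .study_db import (
    CATEGORIES,
    AgeStandard,
    read_age_standard,
    read_hierarchy,
    read_population,
    read_study_table,
    validate_studies,
)
from .synthetic_cohort import make_fixture

log = logging.getLogger("doubleburden")

__all__ = ["run_pipeline", "write_draws", "read_draws", "summarise_draws",
           "classify_countries", "build_report", "PipelineResult"]


# ---------------------------------------------------------------------------
# Draw archive (tidy CSV)


def write_draws(draws: pq.PosteriorDraws, path: "str | Path") -> None:
    """Tidy draw archive: one row per (draw, cell)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d, n = draws.values.shape
    frame = draws.cells.loc[np.tile(np.arange(n), d)].reset_index(drop=True)
    frame.insert(0, "draw", np.repeat(np.arange(d), n))
    frame["prevalence"] = draws.values.ravel()
    frame.to_csv(path, index=False)


def read_draws(path: "str | Path") -> pq.PosteriorDraws:
    df = pd.read_csv(path)
    cell_cols = [c for c in pq.CELL_COLUMNS if c in df.columns]
    n_draws = int(df["draw"].max()) + 1
    first = df[df["draw"] == 0]
    cells = first[cell_cols].reset_index(drop=True)
    values = df["prevalence"].to_numpy().reshape(n_draws, len(cells))
    return pq.PosteriorDraws(values=values, cells=cells)


# ---------------------------------------------------------------------------
# Summarisation


def summarise_draws(draws: pq.PosteriorDraws, standard: AgeStandard,
                    population: "pd.DataFrame | None" = None,
                    baseline_year: "int | None" = None,
                    final_year: "int | None" = None) -> dict[str, pd.DataFrame]:
    """Age-standardise and derive every reported quantity, draw level first.

    Returns tidy frames: ``estimates`` (country,year,sex,quantity,mean,lo,hi
    for low/obese/combined/share), ``probabilities`` (per country and sex:
    change and dominance probabilities plus the percentage-point change), and
    ``correlations`` (change vs baseline level, per sex and category).
    """
    std = pq.age_standardise(draws, standard)
    years = sorted(std.cells["year"].unique())
    y0 = baseline_year if baseline_year is not None else years[0]
    y1 = final_year if final_year is not None else years[-1]

    sexes = sorted(std.cells["sex"].unique())
    countries = sorted(std.cells["country"].unique())

    est_rows = []
    prob_rows = []
    corr_rows = []
    for sex in sexes:
        low = std.select(sex=sex, category="low")
        obese = std.select(sex=sex, category="obese")
        comb = pq.combined_prevalence(low, obese)
        share = pq.obesity_share(low, obese)
        named = {"low": low.drop_columns("category"),
                 "obese": obese.drop_columns("category"),
                 "combined": comb, "share": share}
        for quantity, dr in named.items():
            sf = dr.summary_frame()
            sf["quantity"] = quantity
            est_rows.append(sf[["country", "year", "sex", "quantity", "mean", "lo", "hi"]])

        for country in countries:
            c_comb = comb.select(country=country)
            cy = c_comb.cells["year"].to_numpy()
            v0 = c_comb.values[:, cy == y0][:, 0]
            v1 = c_comb.values[:, cy == y1][:, 0]
            p_inc = pq.posterior_prob_increase(v1, v0)
            p_dec = pq.posterior_prob_decrease(v1, v0)
            lo1 = low.select(country=country)
            ob1 = obese.select(country=country)
            ly = lo1.cells["year"].to_numpy()
            p_ob_gt, p_low_gt = pq.posterior_prob_dominance(
                ob1.values[:, ly == y1][:, 0], lo1.values[:, ly == y1][:, 0])
            delta_pp = float(100.0 * (v1 - v0).mean())
            prob_rows.append({
                "country": country, "sex": sex,
                "p_increase": p_inc, "p_decrease": p_dec,
                "p_obese_gt_low": p_ob_gt, "p_low_gt_obese": p_low_gt,
                "delta_pp": delta_pp,
            })

        # change vs starting level, per category, across countries
        for category in CATEGORIES:
            dr = std.select(sex=sex, category=category)
            mats = []
            for yy in (y0, y1):
                sel = dr.cells["year"].to_numpy() == yy
                sub = dr.values[:, sel]
                order = np.argsort(dr.cells.loc[sel, "country"].to_numpy())
                mats.append(sub[:, order])
            start, end = mats
            if start.shape[1] >= 3:
                summ = pq.correlate_across_countries(end - start, start)
                corr_rows.append({
                    "sex": sex, "category": category,
                    "quantity": "change-vs-start",
                    "r_mean": summ.mean, "r_lo": summ.lo, "r_hi": summ.hi,
                    "n_indeterminate": summ.n_indeterminate,
                })

    return {
        "estimates": pd.concat(est_rows, ignore_index=True),
        "probabilities": pd.DataFrame(prob_rows),
        "correlations": pd.DataFrame(corr_rows),
    }


def classify_countries(probabilities: pd.DataFrame,
                       threshold: float = rpt.PROBABILITY_THRESHOLD) -> pd.DataFrame:
    """Apply the direction / dominance / relevance rules per country row."""
    rows = []
    for _, row in probabilities.iterrows():
        direction = rpt.classify_direction(row["p_increase"], row["p_decrease"], threshold)
        dominance = rpt.classify_dominance(
            row["p_obese_gt_low"], row["p_low_gt_obese"], threshold)
        p_dir = max(row["p_increase"], row["p_decrease"])
        relevant = rpt.classify_relevant_change(row["delta_pp"], p_dir, threshold)
        rows.append({"country": row["country"], "sex": row["sex"],
                     "direction": direction, "dominance": dominance,
                     "relevant_change": relevant})
    return pd.DataFrame(rows)


def build_report(classifications: pd.DataFrame, total_countries: int) -> dict:
    """Counts with rounded percents, per sex, over the full estimation set."""
    out: dict = {"total_countries": total_countries, "by_sex": {}}
    for sex, grp in classifications.groupby("sex"):
        entry = {}
        for direction in ("increase", "decrease", "indeterminate"):
            entry[f"direction_{direction}"] = rpt.count_countries(
                (grp["direction"] == direction).tolist(), total_countries)
        for dominance in ("obesity-dominant", "low-dominant", "indistinguishable"):
            key = "dominance_" + dominance.replace("-", "_")
            entry[key] = rpt.count_countries(
                (grp["dominance"] == dominance).tolist(), total_countries)
        entry["relevant_change"] = rpt.count_countries(
            grp["relevant_change"].tolist(), total_countries)
        out["by_sex"][sex] = entry
    return out


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineResult:
    report: dict
    paths: dict[str, Path]
    diagnostics_clean: bool


def _load_config(config: "Mapping | str | Path") -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _stage(name):
    log.info("stage %s: start", name)
    return time.perf_counter()


def _stage_done(name, t0):
    log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)


def run_pipeline(config: "Mapping | str | Path") -> PipelineResult:
    """Run the configured stages and emit a machine-readable report (JSON)
    plus human-readable tables (CSV).

    Config keys: ``out_dir`` (required); either ``scenario`` (a synthetic
    fixture name) or ``inputs`` (paths to studies/hierarchy/age_standard
    [/population]); ``seed``; optional ``model`` overrides (years, knots,
    mcmc settings); optional ``threshold``.  Re-running an identical config
    reproduces the outputs byte-identically.
    """
    cfg = _load_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    threshold = float(cfg.get("threshold", rpt.PROBABILITY_THRESHOLD))

    paths: dict[str, Path] = {}
    if "scenario" in cfg:
        t0 = _stage("simulate")
        fixture_paths = make_fixture(cfg["scenario"], seed, out_dir / "data")
        paths.update(fixture_paths)
        inputs = {k: str(fixture_paths[k]) for k in
                  ("studies", "hierarchy", "age_standard", "population")}
        _stage_done("simulate", t0)
    else:
        inputs = dict(cfg["inputs"])

    t0 = _stage("load")
    studies = read_study_table(inputs["studies"])
    hierarchy = read_hierarchy(inputs["hierarchy"])
    standard = read_age_standard(inputs["age_standard"])
    population = read_population(inputs["population"]) if inputs.get("population") else None
    violations = validate_studies(studies)
    if not violations.empty:
        raise RuntimeError(
            f"stage load failed: {len(violations)} validation violation(s); "
            f"first: {violations.issues[0]}")
    _stage_done("load", t0)

    t0 = _stage("fit")
    model_cfg = dict(cfg.get("model", {}))
    default_years = (min(o.mid_year for o in studies), max(o.mid_year for o in studies))
    if "truth_meta" in paths:  # synthetic scenario: use the generator's window
        with Path(paths["truth_meta"]).open() as fh:
            default_years = tuple(json.load(fh)["years"])
    years = tuple(model_cfg.get("years") or default_years)
    bands = sorted({(o.age_lo, o.age_hi) for o in studies})
    sexes = tuple(sorted({o.sex for o in studies}))
    spec = ModelSpec(years=(int(years[0]), int(years[1])),
                     age_grid=tuple(bands),
                     knots=tuple(model_cfg.get("knots", (35.0, 50.0, 65.0))))
    mcmc_over = dict(model_cfg.get("mcmc", {}))
    mcmc_over.setdefault("seed", seed)
    spec = spec.with_mcmc(**mcmc_over)
    fits = fit_studies(studies, hierarchy, spec, sexes=sexes)
    for key, fit in fits.items():
        log.info("fit %s: SD acceptance rates %s", key,
                 {k: round(v, 3) for k, v in fit.acceptance.items()})
    _stage_done("fit", t0)

    t0 = _stage("diagnose")
    monitored = {}
    for (category, sex), fit in fits.items():
        a0 = fit.theta[:, :, fit.ctx.slices["a0"].start]
        monitored[f"a0[{category},{sex}]"] = a0
        for i, name in enumerate(fit.sd_names):
            monitored[f"{name}[{category},{sex}]"] = fit.sds[:, :, i]
    diag = convergence_diagnostics(monitored)
    diagnostics_clean = bool(~diag["flagged"].any())
    paths["diagnostics"] = out_dir / "diagnostics.csv"
    diag.to_csv(paths["diagnostics"])
    _stage_done("diagnose", t0)

    t0 = _stage("summarise")
    draws = fits_to_draws(fits)
    paths["draws"] = out_dir / "draws.csv"
    std_draws = pq.age_standardise(draws, standard)
    write_draws(std_draws, paths["draws"])
    tables = summarise_draws(draws, standard, population)
    for name, frame in tables.items():
        paths[name] = out_dir / f"{name}.csv"
        frame.to_csv(paths[name], index=False, float_format="%.10g")
    _stage_done("summarise", t0)

    t0 = _stage("report")
    classifications = classify_countries(tables["probabilities"], threshold)
    paths["classifications"] = out_dir / "classifications.csv"
    classifications.to_csv(paths["classifications"], index=False)
    report = build_report(classifications, total_countries=len(hierarchy.countries))
    report["diagnostics_clean"] = diagnostics_clean
    report["seed"] = seed
    paths["report"] = out_dir / "report.json"
    with paths["report"].open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    # human-readable table
    paths["report_md"] = out_dir / "report.md"
    with paths["report_md"].open("w") as fh:
        fh.write(_report_markdown(report))
    _stage_done("report", t0)

    return PipelineResult(report=report, paths=paths,
                          diagnostics_clean=diagnostics_clean)


def _report_markdown(report: dict) -> str:
    lines = [f"# Double-burden report", "",
             f"Estimation set: {report['total_countries']} countries", ""]
    for sex, entry in sorted(report["by_sex"].items()):
        lines.append(f"## {sex}")
        for key, val in entry.items():
            lines.append(f"- {key}: {val['count']} countries ({val['percent']}%)")
        lines.append("")
    lines.append(f"Diagnostics clean: {report['diagnostics_clean']}")
    lines.append("")
    return "\n".join(lines)
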