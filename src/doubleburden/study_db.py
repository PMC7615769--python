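"""Study-level data: domain types, CSV readers/writers, validation, and the
logit transform that prepares observed prevalences for the likelihood.

The unit of data is one measured prevalence datum (a study crossed with sex
and age band), carrying the design metadata that the hierarchical model uses:
coverage level (national / subnational / community), urbanisation scope, and
sample size.  Readers are deliberately permissive about semantics — they parse
and normalise, while :func:`validate_studies` reports rule violations as data.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CATEGORIES",
    "SEXES",
    "COVERAGE_LEVELS",
    "URBANISATION_LEVELS",
    "StudyObservation",
    "RegionHierarchy",
    "AgeStandard",
    "TransformedObs",
    "ValidationIssue",
    "ValidationReport",
    "SchemaError",
    "RowParseError",
    "read_study_table",
    "write_study_table",
    "read_hierarchy",
    "write_hierarchy",
    "read_age_standard",
    "write_age_standard",
    "read_population",
    "write_population",
    "validate_studies",
    "logit_transform",
    "adult_age_grid",
    "school_age_grid",
]

CATEGORIES = ("low", "obese")
SEXES = ("female", "male")
COVERAGE_LEVELS = ("national", "subnational", "community")
URBANISATION_LEVELS = ("urban", "rural", "mixed")

# Case-insensitive synonyms accepted on input, normalised on read.
_SEX_SYNONYMS = {
    "f": "female", "female": "female", "women": "female", "girls": "female",
    "m": "male", "male": "male", "men": "male", "boys": "male",
}
_COVERAGE_SYNONYMS = {
    "national": "national", "subnational": "subnational",
    "sub-national": "subnational", "community": "community",
}
_URBANISATION_SYNONYMS = {
    "urban": "urban", "rural": "rural", "mixed": "mixed", "both": "mixed",
}

STUDY_COLUMNS = [
    "study_id", "country", "region", "mid_year", "sex", "age_lo", "age_hi",
    "coverage", "urbanisation", "n_sample", "prev_low", "prev_obese",
]


class SchemaError(ValueError):
    """A table is missing a required column or has an unusable header."""


class RowParseError(ValueError):
    """A row could not be parsed; carries the 0-based data row index."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


@dataclass(frozen=True)
class StudyObservation:
    """One measured prevalence datum with its design metadata.

    ``prev`` maps category ("low" for underweight/thinness, "obese" for
    obesity) to an observed prevalence fraction.  Partial category maps are
    allowed: a study may report only one of the two categories.
    """

    study_id: str
    country: str
    mid_year: int
    sex: str
    age_lo: float
    age_hi: float
    coverage: str
    urbanisation: str
    n_sample: int
    prev: Mapping[str, float] = field(default_factory=dict)

    def with_prev(self, **prev: float) -> "StudyObservation":
        return replace(self, prev=dict(prev))


@dataclass(frozen=True)
class RegionHierarchy:
    """Two-level geography: every country belongs to exactly one region."""

    country_to_region: Mapping[str, str]

    def __post_init__(self):
        if not self.country_to_region:
            raise ValueError("hierarchy must contain at least one country")

    @property
    def countries(self) -> list[str]:
        return sorted(self.country_to_region)

    @property
    def regions(self) -> list[str]:
        return sorted(set(self.country_to_region.values()))

    def region_of(self, country: str) -> str:
        try:
            return self.country_to_region[country]
        except KeyError:
            raise KeyError(f"unknown country {country!r}") from None


@dataclass(frozen=True)
class AgeStandard:
    """Ordered, contiguous age bands with positive weights summing to one."""

    bands: tuple[tuple[float, float, float], ...]  # (age_lo, age_hi, weight)

    def __post_init__(self):
        if not self.bands:
            raise ValueError("age standard must have at least one band")
        prev_hi = None
        for lo, hi, w in self.bands:
            if not (lo < hi):
                raise ValueError(f"band ({lo}, {hi}) is not increasing")
            if prev_hi is not None and not math.isclose(lo, prev_hi):
                raise ValueError(
                    f"bands are not contiguous at age {lo} (previous band ends at {prev_hi})"
                )
            if w <= 0:
                raise ValueError(f"band ({lo}, {hi}) has non-positive weight {w}")
            prev_hi = hi
        total = sum(w for _, _, w in self.bands)
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-8):
            raise ValueError(f"weights sum to {total}, expected 1")

    def weight_of(self, age_lo: float, age_hi: float) -> float:
        for lo, hi, w in self.bands:
            if math.isclose(lo, age_lo) and math.isclose(hi, age_hi):
                return w
        raise KeyError(f"band ({age_lo}, {age_hi}) not in age standard")

    @classmethod
    def uniform(cls, bands: Sequence[tuple[float, float]]) -> "AgeStandard":
        w = 1.0 / len(bands)
        return cls(tuple((lo, hi, w) for lo, hi in bands))


@dataclass(frozen=True)
class TransformedObs:
    """A study observation on the logit scale with delta-method variance."""

    y: float
    v: float
    category: str
    study_id: str
    country: str
    mid_year: int
    sex: str
    age_lo: float
    age_hi: float
    coverage: str
    urbanisation: str
    n_sample: int


@dataclass(frozen=True)
class ValidationIssue:
    row_index: int
    rule: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.issues

    def rows_flagged(self) -> set[int]:
        return {i.row_index for i in self.issues}

    def __iter__(self):
        return iter(self.issues)

    def __len__(self):
        return len(self.issues)


def adult_age_grid() -> list[tuple[float, float]]:
    """5-year adult bands 20-24 ... 80-84 plus the open-ended 85+ band.

    Bands are half-open ``[lo, hi)``; 85+ is represented as [85, 90).
    """
    bands = [(float(a), float(a + 5)) for a in range(20, 85, 5)]
    bands.append((85.0, 90.0))
    return bands


def school_age_grid() -> list[tuple[float, float]]:
    """1-year school-age bands 5 ... 19 (half-open)."""
    return [(float(a), float(a + 1)) for a in range(5, 20)]


# ---------------------------------------------------------------------------
# Enum normalisation


def _normalise(value: str, table: Mapping[str, str], what: str, row: int) -> str:
    key = value.strip().lower()
    if key not in table:
        raise RowParseError(row, f"unrecognised {what}: {value!r}")
    return table[key]


# ---------------------------------------------------------------------------
# CSV I/O


def read_study_table(path: str | Path) -> list[StudyObservation]:
    """Parse a studies.csv into observations, preserving row order.

    Raises :class:`SchemaError` if a required column is missing and
    :class:`RowParseError` (with the 0-based data row index) if a cell is
    unparseable.  Semantic invariants (prevalence ranges, category sums,
    sample sizes) are *not* checked here; use :func:`validate_studies`.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header required")
        missing = [c for c in STUDY_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
        out: list[StudyObservation] = []
        for i, row in enumerate(reader):
            out.append(_parse_study_row(row, i))
    return out


def _parse_study_row(row: Mapping[str, str], i: int) -> StudyObservation:
    def num(col: str, caster, what: str):
        raw = (row.get(col) or "").strip()
        try:
            return caster(raw)
        except (TypeError, ValueError):
            raise RowParseError(i, f"unparseable {what} {col}={raw!r}") from None

    prev: dict[str, float] = {}
    for cat, col in (("low", "prev_low"), ("obese", "prev_obese")):
        raw = (row.get(col) or "").strip()
        if raw == "":
            continue
        try:
            prev[cat] = float(raw)
        except ValueError:
            raise RowParseError(i, f"unparseable prevalence {col}={raw!r}") from None

    return StudyObservation(
        study_id=row["study_id"].strip(),
        country=row["country"].strip().upper(),
        mid_year=num("mid_year", lambda s: int(float(s)), "year"),
        sex=_normalise(row["sex"], _SEX_SYNONYMS, "sex", i),
        age_lo=num("age_lo", float, "age"),
        age_hi=num("age_hi", float, "age"),
        coverage=_normalise(row["coverage"], _COVERAGE_SYNONYMS, "coverage", i),
        urbanisation=_normalise(row["urbanisation"], _URBANISATION_SYNONYMS, "urbanisation", i),
        n_sample=num("n_sample", lambda s: int(float(s)), "sample size"),
        prev=prev,
    )


def write_study_table(obs: Iterable[StudyObservation], path: str | Path,
                      region_of=None) -> None:
    """Write observations to CSV with the documented column schema."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(STUDY_COLUMNS)
        for o in obs:
            region = region_of(o.country) if region_of is not None else ""
            w.writerow([
                o.study_id, o.country, region, o.mid_year, o.sex,
                _fmt_age(o.age_lo), _fmt_age(o.age_hi), o.coverage,
                o.urbanisation, o.n_sample,
                _fmt_prev(o.prev.get("low")), _fmt_prev(o.prev.get("obese")),
            ])


def _fmt_age(a: float) -> str:
    return str(int(a)) if float(a).is_integer() else repr(a)


def _fmt_prev(p: float | None) -> str:
    return "" if p is None else repr(float(p))


def read_hierarchy(path: str | Path) -> RegionHierarchy:
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"country", "region"} <= set(reader.fieldnames):
            raise SchemaError(f"{path}: expected columns country,region")
        for i, row in enumerate(reader):
            country = row["country"].strip().upper()
            if country in mapping:
                raise RowParseError(i, f"country {country} mapped twice")
            mapping[country] = row["region"].strip()
    return RegionHierarchy(mapping)


def write_hierarchy(hierarchy: RegionHierarchy, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["country", "region"])
        for c in hierarchy.countries:
            w.writerow([c, hierarchy.country_to_region[c]])


def read_age_standard(path: str | Path) -> AgeStandard:
    path = Path(path)
    bands = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"age_lo", "age_hi", "weight"} <= set(reader.fieldnames):
            raise SchemaError(f"{path}: expected columns age_lo,age_hi,weight")
        for row in reader:
            bands.append((float(row["age_lo"]), float(row["age_hi"]), float(row["weight"])))
    return AgeStandard(tuple(bands))


def write_age_standard(standard: AgeStandard, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["age_lo", "age_hi", "weight"])
        for lo, hi, wt in standard.bands:
            w.writerow([_fmt_age(lo), _fmt_age(hi), repr(wt)])


def read_population(path: str | Path) -> "pd.DataFrame":
    """Population table: country,year,sex,age_lo,age_hi,persons."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"country", "year", "sex", "age_lo", "age_hi", "persons"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(sorted(missing))}")
    if (df["persons"] < 0).any():
        raise ValueError(f"{path}: negative persons counts")
    return df


def write_population(df, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Validation


def validate_studies(obs: Sequence[StudyObservation],
                     window: tuple[int, int] | None = None) -> ValidationReport:
    """Check every observation against the stated invariants.

    Violations are returned as data (row index + rule id), never raised.
    ``window`` optionally bounds mid_year (inclusive).
    """
    report = ValidationReport()

    def flag(i, rule, msg):
        report.issues.append(ValidationIssue(i, rule, msg))

    for i, o in enumerate(obs):
        for cat, p in o.prev.items():
            if not (0.0 <= p <= 1.0):
                flag(i, "prev-range", f"prev[{cat}]={p} outside [0, 1]")
        total = sum(o.prev.values())
        if total > 1.0 + 1e-12:
            flag(i, "category-sum", f"prev[low]+prev[obese]={total} > 1")
        if o.n_sample < 1:
            flag(i, "sample-size", f"n_sample={o.n_sample} < 1")
        if not (o.age_lo < o.age_hi):
            flag(i, "age-order", f"age_lo={o.age_lo} >= age_hi={o.age_hi}")
        if o.sex not in SEXES:
            flag(i, "sex-enum", f"sex={o.sex!r}")
        if o.coverage not in COVERAGE_LEVELS:
            flag(i, "coverage-enum", f"coverage={o.coverage!r}")
        if o.urbanisation not in URBANISATION_LEVELS:
            flag(i, "urbanisation-enum", f"urbanisation={o.urbanisation!r}")
        if window is not None and not (window[0] <= o.mid_year <= window[1]):
            flag(i, "year-window", f"mid_year={o.mid_year} outside {window}")
    return report


# ---------------------------------------------------------------------------
# Logit transform


def _round_half_away(x: float) -> int:
    """Round ties away from zero (3.5 -> 4, -3.5 -> -4)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def logit_transform(obs: StudyObservation, category: str) -> TransformedObs:
    """Observed prevalence -> logit scale with delta-method sampling variance.

    Counts are reconstructed as ``x = round(prev * n)`` (ties away from zero)
    and continuity-corrected: ``p~ = (x + 0.5) / (n + 1)``, which keeps both
    the logit and its variance finite at observed prevalences of 0 or 1.

        y = logit(p~),   v = 1 / (n_eff * p~ * (1 - p~)),  n_eff = n + 1
    """
    if category not in obs.prev:
        raise KeyError(f"category {category!r} not reported by study {obs.study_id}")
    p = obs.prev[category]
    n = obs.n_sample
    x = _round_half_away(p * n)
    x = min(max(x, 0), n)
    n_eff = n + 1
    p_tilde = (x + 0.5) / (n + 1)
    y = math.log(p_tilde / (1.0 - p_tilde))
    v = 1.0 / (n_eff * p_tilde * (1.0 - p_tilde))
    return TransformedObs(
        y=y, v=v, category=category,
        study_id=obs.study_id, country=obs.country, mid_year=obs.mid_year,
        sex=obs.sex, age_lo=obs.age_lo, age_hi=obs.age_hi,
        coverage=obs.coverage, urbanisation=obs.urbanisation, n_sample=n,
    )
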