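"""Reporting conventions: country classification at the 0.80 posterior
probability threshold, the two-percentage-point relevance rule, and country
counts with half-away-from-zero rounded percents."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "PROBABILITY_THRESHOLD",
    "RELEVANT_CHANGE_PP",
    "CountryClassification",
    "classify_direction",
    "classify_relevant_change",
    "classify_dominance",
    "count_countries",
    "round_half_away",
]

PROBABILITY_THRESHOLD = 0.80
RELEVANT_CHANGE_PP = 2.0


def round_half_away(x: float) -> int:
    """Round to the nearest integer with ties going away from zero.

    5.5 -> 6, 88.5 -> 89, -5.5 -> -6.  (Banker's rounding would print the
    wrong percents for exact halves.)
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class CountryClassification:
    """Direction / dominance / relevance labels for one country."""

    country: str
    direction: str     # increase | decrease | indeterminate
    dominance: str     # obesity-dominant | low-dominant | indistinguishable
    relevant_change: bool


def classify_direction(p_increase: float, p_decrease: float,
                       threshold: float = PROBABILITY_THRESHOLD) -> str:
    """Trend direction at the posterior-probability threshold (inclusive:
    "at least" the threshold counts)."""
    if p_increase + p_decrease > 1.0 + 1e-9:
        raise ValueError("p_increase + p_decrease must not exceed 1")
    if p_increase >= threshold and p_decrease >= threshold:
        raise ValueError("both directions cannot meet the threshold")
    if p_increase >= threshold:
        return "increase"
    if p_decrease >= threshold:
        return "decrease"
    return "indeterminate"


def classify_relevant_change(delta_pp: float, p: float,
                             threshold: float = PROBABILITY_THRESHOLD) -> bool:
    """Epidemiologically relevant change: strictly more than two percentage
    points, at the (inclusive) probability threshold."""
    return abs(delta_pp) > RELEVANT_CHANGE_PP and p >= threshold


def classify_dominance(p_ob_gt: float, p_low_gt: float,
                       threshold: float = PROBABILITY_THRESHOLD) -> str:
    """Which burden component dominates; indistinguishable iff neither
    one-sided probability reaches the threshold."""
    if p_ob_gt + p_low_gt > 1.0 + 1e-9:
        raise ValueError("one-sided probabilities must sum to <= 1")
    if p_ob_gt >= threshold:
        return "obesity-dominant"
    if p_low_gt >= threshold:
        return "low-dominant"
    return "indistinguishable"


def count_countries(flags: "Sequence[bool] | Mapping[str, bool]",
                    total: int) -> dict[str, int]:
    """Count true flags and express them as a rounded integer percent of the
    full estimation set (countries without data stay in the denominator)."""
    if total < 1:
        raise ValueError("total must be >= 1")
    values = list(flags.values()) if isinstance(flags, Mapping) else list(flags)
    if len(values) > total:
        raise ValueError(f"{len(values)} flags exceed the estimation set of {total}")
    count = int(sum(bool(v) for v in values))
    return {"count": count, "percent": round_half_away(100.0 * count / total)}
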