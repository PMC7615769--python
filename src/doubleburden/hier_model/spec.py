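"""Model specification: priors, structure toggles, and MCMC settings."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from ..study_db import adult_age_grid

__all__ = ["McmcSettings", "ModelSpec", "SD_NAMES", "ParameterState"]

# Variance (SD) parameters of the model.  Each gets a half-normal prior and,
# unless fixed by the spec, an adaptive log-scale random-walk MH update.
SD_NAMES = (
    "tau_national", "tau_subnational", "tau_community",
    "sd_intercept_region", "sd_intercept_country",
    "sd_slope_region", "sd_slope_country",
    "sd_rw2_global", "sd_rw2_region", "sd_rw2_country",
    "sd_spline_region", "sd_spline_country",
)


@dataclass(frozen=True)
class McmcSettings:
    iterations: int = 2000
    burnin_frac: float = 0.5
    thin: int = 5
    chains: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be positive")
        if not (0.0 <= self.burnin_frac <= 1.0):
            raise ValueError("burnin_frac must be in [0, 1]")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_burn(self) -> int:
        return int(self.iterations * self.burnin_frac)


@dataclass(frozen=True)
class ModelSpec:
    """Everything the sampler needs besides the data.

    ``fixed_sd`` pins a variance parameter: a positive value removes its MH
    update; zero removes the whole deviation group from the model (used by
    the conjugate closed-form oracle and by ablation tests).  Component
    toggles (``include_*``) drop entire structural blocks.
    """

    years: tuple[int, int] = (1990, 2010)
    age_grid: tuple[tuple[float, float], ...] = tuple(adult_age_grid())
    knots: tuple[float, ...] = (35.0, 50.0, 65.0)
    prior_sd: Mapping[str, float] = field(default_factory=lambda: {
        "fixed": 1.0, "offset": 1.0, "urban": 1.0, "spline_global": 1.0})
    halfnormal_scale: Mapping[str, float] = field(
        default_factory=lambda: {name: 1.0 for name in SD_NAMES})
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    include_slope: bool = True
    include_rw2: bool = True
    include_spline: bool = True
    include_study_effects: bool = True
    include_offsets: bool = True
    include_urban: bool = True
    fixed_sd: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.years[1] < self.years[0]:
            raise ValueError("degenerate year range")
        lo = min(b[0] for b in self.age_grid)
        hi = max(b[1] for b in self.age_grid)
        mids = [0.5 * (a + b) for a, b in self.age_grid]
        for kn in self.knots:
            if not (min(mids) < kn < max(mids)):
                raise ValueError(f"knot {kn} outside the age mid-point domain "
                                 f"({min(mids)}, {max(mids)}) for grid {lo}-{hi}")
        for name, v in self.fixed_sd.items():
            if name not in SD_NAMES:
                raise ValueError(f"unknown variance parameter {name!r}")
            if v < 0:
                raise ValueError(f"fixed SD {name} must be >= 0")

    def with_mcmc(self, **kwargs) -> "ModelSpec":
        return replace(self, mcmc=replace(self.mcmc, **kwargs))

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1

    def sd_is_fixed(self, name: str) -> bool:
        return name in self.fixed_sd


@dataclass
class ParameterState:
    """One point in parameter space: all linear effects plus the SDs.

    ``theta`` is the packed vector of linear effects (layout lives on the
    :class:`~doubleburden.hier_model.context.ModelContext`); ``sds`` maps
    variance-parameter names to current SD values.
    """

    theta: np.ndarray
    sds: dict[str, float]

    def copy(self) -> "ParameterState":
        return ParameterState(self.theta.copy(), dict(self.sds))
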