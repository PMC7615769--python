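"""Shared fixtures: synthetic scenarios and (expensive) session-scoped fits."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from doubleburden.hier_model import (
    McmcSettings,
    ModelFit,
    ModelSpec,
    build_context,
    mcmc_fit,
    predict_prevalence,
)
from doubleburden.study_db import StudyObservation, logit_transform
from doubleburden.synthetic_cohort import (
    SCENARIOS,
    default_age_standard,
    sample_true_surface,
    simulate_studies,
)


def make_obs(**overrides) -> StudyObservation:
    """A single valid observation with overridable fields."""
    base = dict(
        study_id="S1", country="AAA", mid_year=2000, sex="female",
        age_lo=20.0, age_hi=25.0, coverage="national", urbanisation="mixed",
        n_sample=500, prev={"low": 0.1, "obese": 0.2},
    )
    base.update(overrides)
    return StudyObservation(**base)


@dataclass
class ScenarioBundle:
    surface: object
    studies: list
    hierarchy: object
    spec: ModelSpec
    weights: np.ndarray
    fits: dict[str, ModelFit]

    def standardised(self, fit_key: str, country: str) -> np.ndarray:
        """(D, T) age-standardised national draws."""
        return predict_prevalence(self.fits[fit_key], country) @ self.weights


def _fit(studies, hierarchy, spec, category, sex="female") -> ModelFit:
    tobs = [logit_transform(o, category) for o in studies if category in o.prev]
    return mcmc_fit(build_context(tobs, hierarchy, spec, category, sex), spec)


def _bundle(scenario: str, seed: int, mcmc: McmcSettings,
            categories=("low",)) -> ScenarioBundle:
    cfg, design = SCENARIOS[scenario](seed)
    surface = sample_true_surface(cfg, seed)
    studies = simulate_studies(surface, design, seed)
    hierarchy = cfg.hierarchy()
    spec = ModelSpec(years=cfg.years, age_grid=cfg.age_grid, knots=cfg.knots,
                     mcmc=mcmc)
    weights = np.array([w for _, _, w in default_age_standard(cfg.age_grid).bands])
    fits = {cat: _fit(studies, hierarchy, spec, cat) for cat in categories}
    return ScenarioBundle(surface=surface, studies=studies, hierarchy=hierarchy,
                          spec=spec, weights=weights, fits=fits)


@pytest.fixture(scope="session")
def recovery_bundle() -> ScenarioBundle:
    return _bundle("recovery", seed=1,
                   mcmc=McmcSettings(iterations=2000, chains=4, seed=3),
                   categories=("low", "obese"))


@pytest.fixture(scope="session")
def crossover_bundle() -> ScenarioBundle:
    return _bundle("crossover", seed=2,
                   mcmc=McmcSettings(iterations=2000, chains=4, seed=5),
                   categories=("low", "obese"))


@pytest.fixture(scope="session")
def shrinkage_bundle() -> ScenarioBundle:
    return _bundle("shrinkage", seed=4,
                   mcmc=McmcSettings(iterations=1200, chains=4, seed=6),
                   categories=("low",))


@pytest.fixture(scope="session")
def smoke_dir(tmp_path_factory):
    from doubleburden.synthetic_cohort import make_fixture

    out = tmp_path_factory.mktemp("smoke")
    return make_fixture("smoke", 1, out)
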