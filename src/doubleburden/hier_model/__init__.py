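"""Bayesian hierarchical meta-regression: model spec, context, sampler,
prediction and diagnostics."""

from .basis import build_age_basis, build_rw2, center_basis
from .context import ModelContext, build_context
from .diagnostics import convergence_diagnostics
from .posterior import log_posterior
from .predict import fits_to_draws, predict_prevalence
from .sampler import ModelFit, mcmc_fit
from .spec import SD_NAMES, McmcSettings, ModelSpec, ParameterState

__all__ = [
    "build_age_basis", "build_rw2", "center_basis",
    "ModelContext", "build_context",
    "convergence_diagnostics",
    "log_posterior",
    "predict_prevalence", "fits_to_draws",
    "ModelFit", "mcmc_fit",
    "ModelSpec", "McmcSettings", "ParameterState", "SD_NAMES",
    "fit_studies",
]


def fit_studies(observations, hierarchy, spec, categories=("low", "obese"),
                sexes=("female", "male")):
    """Transform + fit every requested (category, sex) combination.

    ``observations`` are :class:`~doubleburden.study_db.StudyObservation`
    records; each is logit-transformed per category before fitting.  Returns
    a dict mapping (category, sex) to a :class:`ModelFit`.
    """
    from ..study_db import logit_transform

    fits = {}
    for category in categories:
        transformed = [logit_transform(o, category) for o in observations
                       if category in o.prev]
        for sex in sexes:
            ctx = build_context(transformed, hierarchy, spec, category, sex)
            fits[(category, sex)] = mcmc_fit(ctx, spec)
    return fits
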