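import numpy as np
import pytest
from scipy.stats import halfnorm, norm

from doubleburden.hier_model import (
    McmcSettings,
    ModelFit,
    ModelSpec,
    ParameterState,
    build_context,
    convergence_diagnostics,
    log_posterior,
    mcmc_fit,
    predict_prevalence,
)
from doubleburden.study_db import RegionHierarchy, TransformedObs, logit_transform

from conftest import make_obs


def tobs(y, v, country="AAA", study_id="s1", mid_year=2001, **kw):
    base = dict(category="low", sex="female", age_lo=20.0, age_hi=25.0,
                coverage="national", urbanisation="mixed", n_sample=100)
    base.update(kw)
    return TransformedObs(y=y, v=v, country=country, study_id=study_id,
                          mid_year=mid_year, **base)


INTERCEPT_ONLY = dict(
    include_slope=False, include_rw2=False, include_spline=False,
    include_study_effects=False, include_offsets=False, include_urban=False,
    fixed_sd={"sd_intercept_region": 0.0, "sd_intercept_country": 0.0},
)


def intercept_only_spec(**mcmc_kw) -> ModelSpec:
    return ModelSpec(years=(2000, 2002), age_grid=((20.0, 25.0),), knots=(),
                     mcmc=McmcSettings(**mcmc_kw), **INTERCEPT_ONLY)


@pytest.fixture
def one_country() -> RegionHierarchy:
    return RegionHierarchy({"AAA": "R1"})


class TestLogPosterior:
    def test_zero_studies_equals_log_prior(self, one_country):
        spec = intercept_only_spec()
        ctx = build_context([], one_country, spec, "low", "female")
        state = ParameterState(np.array([0.7]), {})
        assert log_posterior(state, ctx) == pytest.approx(norm.logpdf(0.7, 0, 1))

    def test_tiny_instance_matches_hand_sum(self, one_country):
        # 1 country, 2 studies, intercept-only with study effects: the joint
        # density is summed by hand from scipy building blocks
        spec = ModelSpec(
            years=(2000, 2002), age_grid=((20.0, 25.0),), knots=(),
            include_slope=False, include_rw2=False, include_spline=False,
            include_offsets=False, include_urban=False,
            fixed_sd={"sd_intercept_region": 0.0, "sd_intercept_country": 0.0},
        )
        data = [tobs(0.4, 0.25, study_id="s1"), tobs(-0.2, 0.5, study_id="s2")]
        ctx = build_context(data, one_country, spec, "low", "female")
        a0, e1, e2, tau = 0.3, 0.1, -0.05, 0.4
        theta = np.zeros(ctx.n_params)
        theta[ctx.slices["a0"]] = a0
        theta[ctx.slices["e_study"]] = [e1, e2]
        state = ParameterState(theta, {"tau_national": tau})
        expected = (
            norm.logpdf(0.4, a0 + e1, np.sqrt(0.25))
            + norm.logpdf(-0.2, a0 + e2, np.sqrt(0.5))
            + norm.logpdf(a0, 0, 1)
            + norm.logpdf(e1, 0, tau) + norm.logpdf(e2, 0, tau)
            + halfnorm(scale=1.0).logpdf(tau)
        )
        assert log_posterior(state, ctx) == pytest.approx(expected, rel=1e-12)

    def test_scaling_v_changes_only_likelihood_block(self, one_country):
        spec = intercept_only_spec()
        d1 = [tobs(0.4, 0.25)]
        d2 = [tobs(0.4, 0.5)]
        c1 = build_context(d1, one_country, spec, "low", "female")
        c2 = build_context(d2, one_country, spec, "low", "female")
        state = ParameterState(np.array([0.1]), {})
        analytic = (norm.logpdf(0.4, 0.1, np.sqrt(0.5))
                    - norm.logpdf(0.4, 0.1, np.sqrt(0.25)))
        assert (log_posterior(state, c2) - log_posterior(state, c1)
                == pytest.approx(analytic, rel=1e-12))

    def test_nonpositive_sd_raises(self, one_country):
        spec = ModelSpec(years=(2000, 2002), age_grid=((20.0, 25.0),), knots=(),
                         include_slope=False, include_rw2=False,
                         include_spline=False, include_offsets=False,
                         include_urban=False,
                         fixed_sd={"sd_intercept_region": 0.0,
                                   "sd_intercept_country": 0.0})
        data = [tobs(0.4, 0.25)]
        ctx = build_context(data, one_country, spec, "low", "female")
        theta = np.zeros(ctx.n_params)
        with pytest.raises(ValueError, match="non-positive"):
            log_posterior(ParameterState(theta, {"tau_national": -1.0}), ctx)


class TestSampler:
    def test_conjugate_oracle(self, one_country):
        # prior N(0,1), one obs y=1 with v=0.25: posterior N(0.8, sqrt(0.2))
        spec = intercept_only_spec(iterations=2000, thin=1, chains=4, seed=7)
        ctx = build_context([tobs(1.0, 0.25)], one_country, spec, "low", "female")
        fit = mcmc_fit(ctx, spec)
        draws = fit.param_draws("a0").ravel()
        mc_se = draws.std() / np.sqrt(draws.size)  # draws are iid here
        assert abs(draws.mean() - 0.8) < 3 * mc_se
        assert draws.std() == pytest.approx(np.sqrt(0.2), rel=0.1)

    def test_same_seed_bit_identical(self, one_country):
        spec = intercept_only_spec(iterations=200, chains=2, seed=11)
        ctx = build_context([tobs(1.0, 0.25)], one_country, spec, "low", "female")
        f1 = mcmc_fit(ctx, spec)
        f2 = mcmc_fit(ctx, spec)
        assert np.array_equal(f1.theta, f2.theta)
        assert np.array_equal(f1.sds, f2.sds)

    def test_full_burnin_raises(self, one_country):
        spec = intercept_only_spec(iterations=100, burnin_frac=1.0)
        ctx = build_context([tobs(1.0, 0.25)], one_country, spec, "low", "female")
        with pytest.raises(ValueError, match="no retained draws"):
            mcmc_fit(ctx, spec)

    def test_prior_only_fit_warns(self, one_country):
        spec = intercept_only_spec(iterations=100, chains=2)
        ctx = build_context([], one_country, spec, "low", "female")
        with pytest.warns(UserWarning, match="prior-only"):
            fit = mcmc_fit(ctx, spec)
        draws = fit.param_draws("a0").ravel()
        assert abs(draws.mean()) < 0.5  # prior is N(0, 1)

    def test_acceptance_rates_near_target(self, recovery_bundle):
        rates = recovery_bundle.fits["low"].acceptance
        assert rates, "expected adaptive MH acceptance rates"
        for name, rate in rates.items():
            assert 0.2 < rate < 0.7, (name, rate)

    def test_rw2_draws_orthogonal_to_trend(self, recovery_bundle):
        # identifiability: RW2 curves sum to 0 and are trend-free, per draw
        fit = recovery_bundle.fits["low"]
        ctx = fit.ctx
        z = ctx.rw2.z
        t = np.arange(z.shape[0], dtype=float)
        for name in ("w_global", "w_country"):
            w = fit.param_draws(name)[:50]
            q = ctx.rw2.dim
            curves = w.reshape(50, -1, q) @ z.T
            assert np.max(np.abs(curves.sum(axis=-1))) < 1e-8
            trend = (curves * (t - t.mean())).sum(axis=-1)
            assert np.max(np.abs(trend)) < 1e-7


class TestPredict:
    def test_all_zero_draws_give_half(self, one_country):
        spec = intercept_only_spec(iterations=10, chains=2)
        ctx = build_context([tobs(1.0, 0.25)], one_country, spec, "low", "female")
        fit = ModelFit(ctx=ctx, spec=spec, theta=np.zeros((2, 5, ctx.n_params)),
                       sds=np.zeros((2, 5, 0)), sd_names=())
        out = predict_prevalence(fit, "AAA")
        assert np.all(out == 0.5)

    def test_output_strictly_inside_unit_interval(self, recovery_bundle):
        out = predict_prevalence(recovery_bundle.fits["low"], "C03")
        assert np.all(out > 0) and np.all(out < 1)

    def test_unknown_country_raises(self, one_country):
        spec = intercept_only_spec(iterations=10, chains=2)
        ctx = build_context([tobs(1.0, 0.25)], one_country, spec, "low", "female")
        fit = ModelFit(ctx=ctx, spec=spec, theta=np.zeros((2, 5, ctx.n_params)),
                       sds=np.zeros((2, 5, 0)), sd_names=())
        with pytest.raises(KeyError, match="ZZZ"):
            predict_prevalence(fit, "ZZZ")


class TestDiagnostics:
    def test_iid_chains_rhat_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((4, 1000))
        diag = convergence_diagnostics({"x": chains})
        assert diag.loc["x", "rhat"] < 1.01
        assert not diag.loc["x", "flagged"]

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((2, 500)) + np.array([[-10.0], [10.0]])
        diag = convergence_diagnostics({"x": chains})
        assert diag.loc["x", "rhat"] > 1.05
        assert diag.loc["x", "flagged"]

    def test_constant_chains_flagged_not_crashed(self):
        diag = convergence_diagnostics({"x": np.ones((2, 100))})
        assert diag.loc["x", "flagged"]

    def test_single_chain_raises(self):
        with pytest.raises(ValueError, match="2 chains"):
            convergence_diagnostics({"x": np.zeros((1, 100))})


class TestContextValidation:
    def test_chains_requirement(self):
        spec = intercept_only_spec()
        assert spec.mcmc.chains >= 2

    def test_observation_off_grid_raises(self, one_country):
        spec = intercept_only_spec()
        bad = tobs(0.0, 0.1, age_lo=50.0, age_hi=55.0)
        with pytest.raises(ValueError, match="age band"):
            build_context([bad], one_country, spec, "low", "female")

    def test_observation_outside_window_raises(self, one_country):
        spec = intercept_only_spec()
        with pytest.raises(ValueError, match="window"):
            build_context([tobs(0.0, 0.1, mid_year=1950)], one_country,
                          spec, "low", "female")

    def test_basis_partition_of_unity_in_context(self, recovery_bundle):
        ctx = recovery_bundle.fits["low"].ctx
        assert np.allclose(ctx.basis_raw.sum(axis=1), 1.0, atol=1e-10)
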