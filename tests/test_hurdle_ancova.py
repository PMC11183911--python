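"""Design building, log-posterior oracles, priors, and sampler behavior."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import optimize

from woundhurdle.hurdle_ancova import (
    PARAM_NAMES,
    DesignMatrix,
    FitConfig,
    build_design,
    default_priors,
    fit,
    log_likelihood,
    log_posterior,
)
from woundhurdle.likelihoods import HurdleGammaParams, hurdle_gamma_logpdf, inv_logit
from woundhurdle.synthetic_cohort import CohortTable, WoundRecord, generate_cohort


def _toy_cohort(pre, post, arms):
    return CohortTable(
        [
            WoundRecord(f"S{i}", int(a), float(p), float(y), 3, 30)
            for i, (p, y, a) in enumerate(zip(pre, post, arms))
        ]
    )


class TestBuildDesign:
    def test_standardization(self):
        cohort = _toy_cohort([2, 4, 6], [0, 1, 2], [0, 1, 0])
        design = build_design(cohort)
        assert np.mean(design.pre_std) == pytest.approx(0.0, abs=1e-12)
        assert np.std(design.pre_std, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_back_transform_exact(self, small_cohort):
        design = build_design(small_cohort)
        pre = small_cohort.to_dataframe()["pre_area_cm2"].to_numpy()
        np.testing.assert_allclose(design.pre, pre, rtol=0, atol=1e-12)

    def test_reference_cohort_coding(self, small_cohort):
        design = build_design(small_cohort)
        assert len(design) == 41
        assert int(design.group.sum()) == 23

    def test_single_arm_rejected(self):
        with pytest.raises(ValueError, match="both arms"):
            build_design(_toy_cohort([2, 4], [0, 1], [1, 1]))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            build_design(_toy_cohort([3, 3, 3], [0, 1, 2], [0, 1, 0]))


class TestLogPosterior:
    def test_equals_per_record_sum(self, small_cohort):
        """Likelihood part must equal the brute-force sum of per-record terms."""
        design = build_design(small_cohort)
        priors = default_priors(design)
        theta = np.array([-0.4, 0.3, 0.6, 2.1, -0.2, 0.4, math.log(1.7)])
        k = math.exp(theta[6])
        expected = 0.0
        for g, z, y in zip(design.group, design.pre_std, design.y):
            pi = inv_logit(theta[0] + theta[1] * g + theta[2] * z)
            mu = math.exp(theta[3] + theta[4] * g + theta[5] * z)
            expected += hurdle_gamma_logpdf(y, HurdleGammaParams(pi, mu, k))
        assert log_likelihood(theta, design) == pytest.approx(expected, abs=1e-10)
        # and log_posterior differs from the likelihood only by the prior terms
        prior_part = log_posterior(theta, design, priors) - log_likelihood(theta, design)
        theta2 = theta + np.array([0.1, 0, 0, 0, 0, 0, 0])
        prior_part2 = log_posterior(theta2, design, priors) - log_likelihood(theta2, design)
        loc, scale = priors.hurdle_intercept
        expected_diff = (
            -0.5 * ((theta2[0] - loc) / scale) ** 2 + 0.5 * ((theta[0] - loc) / scale) ** 2
        )
        assert prior_part2 - prior_part == pytest.approx(expected_diff, abs=1e-10)

    def test_closed_wound_branch_isolation(self):
        design = DesignMatrix(
            group=np.array([1.0]), pre_std=np.array([0.7]), y=np.array([0.0]),
            center=10.0, scale=3.0,
        )
        theta = np.array([0.2, -0.5, 0.3, 1.0, 0.0, 0.0, 0.0])
        eta = theta[0] + theta[1] * 1.0 + theta[2] * 0.7
        assert log_likelihood(theta, design) == pytest.approx(
            math.log(1 - inv_logit(eta)), abs=1e-12
        )

    def test_mle_of_area_intercept_is_group_mean(self, rng):
        """With a flat baseline, exp(theta-hat) is the mean positive area per arm."""
        n = 40
        arms = np.repeat([0, 1], n)
        y = np.concatenate([rng.gamma(2.0, 5.0 / 2.0, n), rng.gamma(2.0, 9.0 / 2.0, n)])
        design = DesignMatrix(
            group=arms.astype(float), pre_std=np.zeros(2 * n), y=y, center=1.0, scale=1.0
        )
        res = optimize.minimize(
            lambda th: -log_likelihood(th, design),
            np.array([1.0, 0.0, 0.0, 1.5, 0.0, 0.0, 0.5]),
            method="Nelder-Mead",
            options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-12},
        )
        theta_hat = res.x
        assert math.exp(theta_hat[3]) == pytest.approx(np.mean(y[arms == 0]), rel=1e-4)
        assert math.exp(theta_hat[3] + theta_hat[4]) == pytest.approx(
            np.mean(y[arms == 1]), rel=1e-4
        )

    def test_rejects_non_finite_theta(self, small_cohort):
        design = build_design(small_cohort)
        with pytest.raises(ValueError):
            log_posterior(np.array([np.nan, 0, 0, 0, 0, 0, 0]), design, default_priors(design))


class TestDefaultPriors:
    def test_area_intercept_scale_covers_data_spread(self, small_cohort):
        design = build_design(small_cohort)
        priors = default_priors(design)
        y_pos = design.y[design.y > 0]
        assert priors.area_intercept[1] >= np.std(np.log(y_pos), ddof=1)

    def test_symmetric_in_arm_labels(self, small_cohort):
        priors = default_priors(build_design(small_cohort))
        assert priors.hurdle_group[0] == 0.0
        assert priors.area_group[0] == 0.0

    def test_prior_predictive_closure_spans_wide_range(self, small_cohort, rng):
        design = build_design(small_cohort)
        priors = default_priors(design)
        psis = []
        for _ in range(2000):
            a1 = rng.normal(*priors.hurdle_intercept)
            g = rng.normal(*priors.hurdle_baseline)
            psis.append(1 - np.mean(inv_logit(a1 + g * design.pre_std)))
        lo, hi = np.percentile(psis, [2.5, 97.5])
        assert lo < 0.05 and hi > 0.95


class TestFit:
    def test_retains_4000_draws_by_default(self, small_cohort):
        design = build_design(small_cohort)
        draws = fit(design, config=FitConfig(seed=1))
        assert draws.draws.shape == (4, 1000, 7)
        assert draws.n_total == 4000
        assert draws.param_names == PARAM_NAMES
        assert np.all(draws.get("gamma_shape") > 0)
        assert int(np.sum(draws.divergences)) == 0

    def test_seed_determinism(self, small_cohort, quick_config):
        design = build_design(small_cohort)
        a = fit(design, config=quick_config)
        b = fit(design, config=quick_config)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_parameter_recovery(self, calibrated_params):
        """Posterior concentrates near the generative truth at n=800/arm."""
        cohort = generate_cohort(calibrated_params, (800, 800), seed=21)
        design = build_design(cohort)
        draws = fit(design, config=FitConfig(n_draws_per_chain=500, n_warmup=500, seed=6))
        p = calibrated_params
        # the fitter standardizes by the sample mean/SD; map truth accordingly
        shift = (design.center - p.baseline_mean) / p.baseline_sd
        ratio = design.scale / p.baseline_sd
        truth = {
            "hurdle_intercept": p.hurdle_intercept + p.hurdle_baseline * shift,
            "hurdle_group": p.hurdle_group,
            "hurdle_baseline": p.hurdle_baseline * ratio,
            "area_intercept": p.area_intercept + p.area_baseline * shift,
            "area_group": p.area_group,
            "area_baseline": p.area_baseline * ratio,
            "gamma_shape": p.gamma_shape,
        }
        for name, true_value in truth.items():
            sample = draws.flat(name)
            z = abs(np.mean(sample) - true_value) / np.std(sample)
            assert z < 4.0, f"{name}: posterior mean {np.mean(sample):.3f} vs truth {true_value:.3f}"

    def test_posterior_contraction_in_group_effect(self, calibrated_params):
        """Posterior SD of the treatment effect shrinks as the cohort grows."""
        sds = []
        for n, seed in [(50, 31), (200, 32), (800, 33)]:
            cohort = generate_cohort(calibrated_params, (n, n), seed=seed)
            design = build_design(cohort)
            draws = fit(design, config=FitConfig(n_draws_per_chain=400, n_warmup=400, seed=8))
            sds.append(np.std(draws.flat("area_group")))
        assert sds[0] > sds[1] > sds[2]

    def test_unadjusted_variant_drops_baseline_terms(self, small_cohort, quick_config):
        design = build_design(small_cohort)
        draws = fit(design, config=quick_config, include_baseline=False)
        assert "hurdle_baseline" not in draws.param_names
        assert "area_baseline" not in draws.param_names
        assert draws.draws.shape == (2, 100, 5)

    def test_matches_independent_ensemble_sampler(self, calibrated_params):
        """Cross-check posterior means against emcee on the same log-posterior."""
        emcee = pytest.importorskip("emcee")
        cohort = generate_cohort(calibrated_params, (120, 120), seed=41)
        design = build_design(cohort)
        priors = default_priors(design)
        draws = fit(design, priors, FitConfig(n_draws_per_chain=500, n_warmup=500, seed=9))

        ndim, nwalkers = 7, 32
        rng = np.random.default_rng(10)
        p0 = np.array(
            [[-0.5, 0, 0.5, 2.5, 0, 0.5, 0.4] + 0.05 * rng.normal(size=ndim)
             for _ in range(nwalkers)]
        )
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, lambda th: log_posterior(th, design, priors)
        )
        state = sampler.run_mcmc(p0, 2000, progress=False)
        chain = sampler.get_chain(discard=1000, flat=True)
        for i, name in enumerate(PARAM_NAMES):
            ours = draws.flat(name) if name != "gamma_shape" else np.log(draws.flat(name))
            theirs = chain[:, i]
            tol = 4 * np.std(theirs) / np.sqrt(50) + 4 * np.std(ours) / np.sqrt(50)
            assert np.mean(ours) == pytest.approx(np.mean(theirs), abs=max(tol, 0.05)), name


def test_fit_config_validation():
    with pytest.raises(ValueError):
        FitConfig(n_chains=0)
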