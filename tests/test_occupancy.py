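"""Marginalized likelihood, priors, sampler and convergence diagnostics."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import halfnorm, norm

from helpers import enumeration_loglik
from fireocc import studies, synthetic
from fireocc.exceptions import (
    InvalidArgumentError,
    ShapeError,
)
from fireocc.occupancy import (
    DetectionHistory,
    ModelSpec,
    ParamLayout,
    fit,
    log_posterior,
    period_loglik,
    rhat,
)


class TestPeriodLoglik:
    def test_certain_occupancy(self):
        # psi ~ 1: the marginal reduces to the detection product 0.25
        val = period_loglik([1, 0], 1 - 1e-14, [0.5, 0.5])
        np.testing.assert_allclose(val, np.log(0.25), atol=1e-10)

    def test_all_zero_history_closed_form(self):
        val = period_loglik([0, 0], 0.5, [0.5, 0.5])
        np.testing.assert_allclose(val, np.log(0.625))

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(1000):
            J = rng.integers(1, 18)
            y = rng.integers(0, 2, size=J)
            psi = rng.uniform(0.01, 0.99)
            p = rng.uniform(0.01, 0.99, size=J)
            np.testing.assert_allclose(
                period_loglik(y, psi, p), enumeration_loglik(y, psi, p),
                rtol=0, atol=1e-12)

    def test_invariant_to_night_permutation(self, rng):
        y = np.array([1, 0, 0, 1, 0])
        p = rng.uniform(0.1, 0.9, size=5)
        perm = rng.permutation(5)
        np.testing.assert_allclose(period_loglik(y, 0.7, p),
                                   period_loglik(y[perm], 0.7, p[perm]))

    @pytest.mark.parametrize("psi,p", [
        (0.0, [0.5]), (1.0, [0.5]), (0.5, [0.0]), (0.5, [1.0]), (-0.1, [0.5]),
    ])
    def test_domain_errors(self, psi, p):
        with pytest.raises(InvalidArgumentError):
            period_loglik([0], psi, p)


def tiny_model():
    """One period, two nights, one site/area; fully hand-checkable."""
    X_det = np.array([[1.0, 0.5], [1.0, -0.5]])
    X_occ = np.array([[1.0, 2.0]])
    spec = ModelSpec(X_det=X_det, X_occ=X_occ,
                     obs_period=np.zeros(2, dtype=int),
                     site_idx=np.zeros(1, dtype=int),
                     area_idx=np.zeros(1, dtype=int),
                     det_columns=("intercept", "x"),
                     occ_columns=("intercept", "w"))
    hist = DetectionHistory(y=np.array([1, 0]), obs_period=np.zeros(2, int),
                            n_periods=1)
    return spec, hist


class TestLogPosterior:
    def test_hand_computed_toy(self):
        spec, hist = tiny_model()
        alpha = np.array([0.2, -0.3])
        beta = np.array([0.4, 0.1])
        b_s, b_a = np.array([0.15]), np.array([-0.05])
        ls_s, ls_a = np.log(0.6), np.log(0.8)
        params = ParamLayout(2, 2, 1, 1).pack(alpha, beta, b_s, b_a, ls_s, ls_a)

        p = expit(spec.X_det @ alpha)
        psi = expit(spec.X_occ @ beta + b_s[0] + b_a[0])
        expected = np.log(psi[0] * p[0] * (1 - p[1]))  # detected period
        sd = spec.priors.fixed_effect_sd
        expected += norm.logpdf(alpha, 0, sd).sum() + norm.logpdf(beta, 0, sd).sum()
        for b, ls, scale in ((b_s, ls_s, 1.0), (b_a, ls_a, 1.0)):
            expected += norm.logpdf(b, 0, np.exp(ls)).sum()
            expected += halfnorm.logpdf(np.exp(ls), scale=scale) + ls
        np.testing.assert_allclose(log_posterior(params, spec, hist),
                                   expected, atol=1e-10)

    def test_zero_coefficient_ignores_its_covariate(self):
        spec, hist = tiny_model()
        params = ParamLayout(2, 2, 1, 1).pack(
            np.array([0.3, 0.0]), np.array([0.2, 0.0]),
            np.zeros(1), np.zeros(1), 0.0, 0.0)
        base = log_posterior(params, spec, hist)
        spec.X_det[:, 1] += 7.0  # covariate with zero coefficient
        spec.X_occ[:, 1] -= 3.0
        np.testing.assert_allclose(log_posterior(params, spec, hist), base)

    def test_prior_mode_at_zero_fixed_effects(self, rng):
        spec, hist = tiny_model()
        layout = ParamLayout(2, 2, 1, 1)

        def log_prior_only(alpha, beta):
            params = layout.pack(alpha, beta, np.zeros(1), np.zeros(1), 0.0, 0.0)
            ll = period_loglik(hist.y, expit(spec.X_occ[0] @ beta),
                               expit(spec.X_det @ alpha))
            return log_posterior(params, spec, hist) - ll

        at_zero = log_prior_only(np.zeros(2), np.zeros(2))
        for _ in range(20):
            perturbed = log_prior_only(rng.normal(size=2), rng.normal(size=2))
            assert perturbed <= at_zero


class TestRhat:
    def test_well_mixed_chains_near_one(self, rng):
        draws = rng.normal(size=(2, 10_000))
        assert rhat(draws) < 1.01

    def test_separated_chains_flagged(self, rng):
        draws = np.stack([rng.normal(0, 0.1, 1000), rng.normal(3, 0.1, 1000)])
        assert rhat(draws) > 1.5

    def test_single_chain_rejected(self):
        with pytest.raises(InvalidArgumentError):
            rhat(np.zeros((1, 100)))

    def test_constant_chains_return_sentinel(self):
        assert np.isnan(rhat(np.ones((3, 100))))

    def test_agrees_with_reference_implementation(self, rng):
        import arviz as az
        draws = rng.normal(size=(4, 500)) + np.linspace(0, 1, 4)[:, None]
        ours = rhat(draws)
        split = float(az.rhat(az.convert_to_dataset(draws), method="split")["x"])
        np.testing.assert_allclose(ours, split, rtol=1e-10)
        # the rank-normalized variant should agree closely on Gaussian draws
        rank = float(az.rhat(az.convert_to_dataset(draws))["x"])
        np.testing.assert_allclose(ours, rank, atol=0.05)


class TestFit:
    def test_intercept_recovery_on_null_model(self):
        # alpha0 = beta0 = 0, no covariate effects, 500 periods
        rng = np.random.default_rng(21)
        dm = studies.simple_design_matrices(rng, n_periods=500,
                                            nights_per_period=6)
        params = synthetic.TrueParameters(alpha=np.zeros(7), beta=np.zeros(6),
                                          sigma_site=0.0, sigma_area=0.0)
        hist, _ = synthetic.simulate_detections(dm, params, seed=22)
        post = fit(ModelSpec.from_design(dm), hist, chains=3,
                   iterations=1500, warmup=750, seed=23)
        assert abs(post.stacked("alpha")[:, 0].mean()) < 0.25
        assert abs(post.stacked("beta")[:, 0].mean()) < 0.25
        assert post.psi.min() > 0 and post.psi.max() < 1

    def test_duplicating_data_shrinks_posterior_sd(self):
        rng = np.random.default_rng(31)
        dm = studies.simple_design_matrices(rng, n_periods=100,
                                            nights_per_period=4, n_sites=20,
                                            n_years=5)
        params = synthetic.TrueParameters(
            alpha=np.full(7, 0.2), beta=np.full(6, 0.2),
            sigma_site=0.0, sigma_area=0.0)
        hist, _ = synthetic.simulate_detections(dm, params, seed=32)

        from fireocc.covariates import DesignMatrices
        dup = DesignMatrices(
            X_det=np.vstack([dm.X_det, dm.X_det]),
            X_occ=np.vstack([dm.X_occ, dm.X_occ]),
            obs_period=np.concatenate([dm.obs_period,
                                       dm.obs_period + dm.n_periods]),
            site_idx=np.concatenate([dm.site_idx, dm.site_idx]),
            area_idx=np.concatenate([dm.area_idx, dm.area_idx]),
        )
        hist2 = DetectionHistory(y=np.concatenate([hist.y, hist.y]),
                                 obs_period=dup.obs_period,
                                 n_periods=dup.n_periods)
        post1 = fit(ModelSpec.from_design(dm), hist, chains=2,
                    iterations=1500, warmup=750, seed=33)
        post2 = fit(ModelSpec.from_design(dup), hist2, chains=2,
                    iterations=1500, warmup=750, seed=34)
        sd1 = np.concatenate([post1.stacked("alpha").std(axis=0),
                              post1.stacked("beta").std(axis=0)])
        sd2 = np.concatenate([post2.stacked("alpha").std(axis=0),
                              post2.stacked("beta").std(axis=0)])
        assert np.all(sd2 < sd1)

    def test_posterior_predictive_naive_detection_rate(self):
        # simulated naive detection frequency from draws matches the data
        rng = np.random.default_rng(41)
        dm = studies.simple_design_matrices(rng, n_periods=300,
                                            nights_per_period=6,
                                            n_sites=60, n_years=5)
        params = synthetic.TrueParameters(
            alpha=studies.RECOVERY_ALPHA, beta=studies.RECOVERY_BETA,
            sigma_site=0.2, sigma_area=0.2)
        hist, _ = synthetic.simulate_detections(dm, params, seed=42)
        post = fit(ModelSpec.from_design(dm), hist, chains=2,
                   iterations=1500, warmup=750, seed=43)
        psi = post.psi_stacked()
        q = post.q_miss_stacked()
        sim_rate = (psi * (1 - q)).mean()  # P(>=1 detection) per period
        obs_rate = hist.naive_occupancy()
        mc_se = np.sqrt(obs_rate * (1 - obs_rate) / hist.n_periods)
        assert abs(sim_rate - obs_rate) < 3 * mc_se

    def test_reproducible_given_seed(self, small_design_matrices):
        params = synthetic.TrueParameters(alpha=np.zeros(7), beta=np.zeros(6))
        hist, _ = synthetic.simulate_detections(small_design_matrices, params,
                                                seed=3)
        spec = ModelSpec.from_design(small_design_matrices)
        p1 = fit(spec, hist, chains=2, iterations=300, warmup=200, seed=7)
        p2 = fit(spec, hist, chains=2, iterations=300, warmup=200, seed=7)
        np.testing.assert_array_equal(p1.draws["beta"], p2.draws["beta"])

    def test_history_spec_mismatch_raises(self, small_design_matrices):
        spec = ModelSpec.from_design(small_design_matrices)
        hist = DetectionHistory(y=np.zeros(3, int),
                                obs_period=np.arange(3), n_periods=3)
        with pytest.raises(ShapeError):
            fit(spec, hist, chains=2, iterations=20, warmup=10, seed=0)
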