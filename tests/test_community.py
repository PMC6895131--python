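"""Richness surfaces, detection-corrected occurrence and Jaccard beta diversity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from helpers import brute_force_beta_summary
from fireocc.community import (
    beta_summary,
    conditional_occurrence_prob,
    draw_occurrence_matrix,
    jaccard_dissimilarity,
    pairwise_jaccard,
    richness_curve,
    severity_class,
)
from fireocc.exceptions import (
    DataValidationError,
    InvalidArgumentError,
    ShapeError,
)
from fireocc.occupancy import DetectionHistory, OccupancyPosterior


def fake_posterior(beta_draws, psi=None, q_miss=None):
    """Minimal posterior container for diversity tests."""
    beta_draws = np.asarray(beta_draws, float)[None]  # one chain
    n = beta_draws.shape[1]
    if psi is None:
        psi = np.full((1, n, 1), 0.5)
    if q_miss is None:
        q_miss = np.full_like(psi, 0.25)
    return OccupancyPosterior(
        draws={"beta": beta_draws}, psi=np.asarray(psi, float),
        q_miss=np.asarray(q_miss, float), log_lik=np.zeros_like(psi),
        rhat={}, accept_rates={},
    )


class TestSeverityClasses:
    @pytest.mark.parametrize("sev,label", [
        (0.0, "unchanged"), (0.5, "low"), (25.0, "low"), (25.1, "moderate"),
        (75.0, "moderate"), (75.1, "high"), (100.0, "high"),
    ])
    def test_boundaries(self, sev, label):
        assert severity_class(sev) == label

    def test_out_of_range(self):
        with pytest.raises(InvalidArgumentError):
            severity_class(101.0)


class TestRichnessCurve:
    def test_constant_half_probability_species(self):
        posts = {f"sp{i}": fake_posterior(np.zeros((50, 6))) for i in range(4)}
        rs = richness_curve(posts, np.linspace(0, 100, 5))
        np.testing.assert_allclose(rs.draws, 2.0)  # S/2 with S = 4
        assert (rs.summary["hi90"] - rs.summary["lo90"]).max() == 0.0

    def test_single_null_species_flat_at_half(self):
        rs = richness_curve({"sp": fake_posterior(np.zeros((50, 6)))},
                            [0.0, 50.0, 100.0])
        np.testing.assert_allclose(rs.summary["mean"], 0.5)

    def test_matches_closed_form_for_known_coefficients(self, rng):
        betas = {f"sp{i}": rng.normal(0, 0.5, size=(1, 6)) for i in range(3)}
        posts = {sp: fake_posterior(np.repeat(b, 40, axis=0))
                 for sp, b in betas.items()}
        centers = {"severity": {"center": 50.0, "scale": 25.0}}
        sev = np.linspace(0, 100, 6)
        pyro = np.array([-2.0, 0.0, 2.0])
        rs = richness_curve(posts, sev, pyro, covariate_centers=centers)
        s = (sev - 50.0) / 25.0
        expected = sum(
            expit(b[0, 0] + b[0, 3] * s[:, None] + b[0, 4] * (s**2)[:, None]
                  + b[0, 5] * pyro[None, :])
            for b in betas.values()
        )
        np.testing.assert_allclose(rs.draws[0], expected, atol=1e-12)
        assert rs.draws.min() >= 0 and rs.draws.max() <= 3

    def test_point_mass_draws_never_widen_intervals(self, rng):
        beta = rng.normal(0, 0.8, size=(200, 6))
        full = richness_curve({"sp": fake_posterior(beta)}, [0, 50, 100])
        point = richness_curve(
            {"sp": fake_posterior(np.tile(beta.mean(axis=0), (200, 1)))},
            [0, 50, 100])
        w_full = full.summary["hi90"] - full.summary["lo90"]
        w_point = point.summary["hi90"] - point.summary["lo90"]
        assert np.all(w_point.to_numpy() <= w_full.to_numpy() + 1e-12)

    def test_severity_outside_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            richness_curve({"sp": fake_posterior(np.zeros((50, 6)))}, [0, 120])


class TestOccurrenceDraws:
    def test_conditional_probability_bayes_rule(self):
        # psi = 0.5, two undetected nights at p = 0.5: q = 0.25
        prob = conditional_occurrence_prob(
            np.array([0.5]), np.array([0.25]), np.array([False]))
        np.testing.assert_allclose(prob, [0.125 / 0.625])  # 0.2

    def test_detected_periods_are_occupied_with_certainty(self):
        prob = conditional_occurrence_prob(
            np.array([0.01]), np.array([0.9]), np.array([True]))
        assert prob[0] == 1.0

    def test_draws_match_conditional_frequency(self):
        n_periods, n_draws = 5, 4000
        hist = DetectionHistory(
            y=np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 0]),
            obs_period=np.repeat(np.arange(n_periods), 2),
            n_periods=n_periods)
        post = fake_posterior(
            np.zeros((n_draws, 6)),
            psi=np.full((1, n_draws, n_periods), 0.5),
            q_miss=np.full((1, n_draws, n_periods), 0.25))
        rng = np.random.default_rng(0)
        zs = np.stack([
            draw_occurrence_matrix({"sp": post}, {"sp": hist}, d, rng)[:, 0]
            for d in range(n_draws)
        ])
        assert np.all(zs[:, 0] == 1)  # detected period
        freq = zs[:, 1:].mean()
        se = np.sqrt(0.2 * 0.8 / (n_draws * (n_periods - 1)))
        assert abs(freq - 0.2) < 4 * se

    def test_near_zero_occupancy_without_detection(self):
        hist = DetectionHistory(y=np.zeros(2, int),
                                obs_period=np.zeros(2, int), n_periods=1)
        post = fake_posterior(np.zeros((200, 6)),
                              psi=np.full((1, 200, 1), 1e-9),
                              q_miss=np.full((1, 200, 1), 0.25))
        z = draw_occurrence_matrix({"sp": post}, {"sp": hist}, 0,
                                   np.random.default_rng(1))
        assert z[0, 0] == 0

    def test_species_mismatch_raises(self):
        post = fake_posterior(np.zeros((200, 6)))
        hist = DetectionHistory(y=np.zeros(1, int),
                                obs_period=np.zeros(1, int), n_periods=1)
        with pytest.raises(ShapeError):
            draw_occurrence_matrix({"a": post}, {"b": hist}, 0)


class TestJaccard:
    def test_fixture_examples(self):
        assert jaccard_dissimilarity([1, 1, 1, 0], [0, 1, 1, 1]) == 0.5
        assert jaccard_dissimilarity([1, 0, 1], [1, 0, 1]) == 0.0
        assert jaccard_dissimilarity([1, 1, 0], [0, 0, 1]) == 1.0
        assert jaccard_dissimilarity([0, 0], [0, 0]) == 0.0  # both empty

    def test_non_binary_rejected(self):
        with pytest.raises(DataValidationError):
            jaccard_dissimilarity([0, 2], [0, 1])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(1, 8), st.integers(0, 2**31 - 1))
    def test_symmetry_triangle_inequality_and_range(self, n_species, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.integers(0, 2, size=(3, n_species))
        dab = jaccard_dissimilarity(a, b)
        dba = jaccard_dissimilarity(b, a)
        dac = jaccard_dissimilarity(a, c)
        dcb = jaccard_dissimilarity(c, b)
        assert dab == dba
        assert 0.0 <= dab <= 1.0
        assert dab <= dac + dcb + 1e-12

    def test_pairwise_matrix_matches_scalar_loop(self, rng):
        occ = rng.integers(0, 2, size=(12, 6))
        D = pairwise_jaccard(occ)
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)
        for i in range(12):
            for j in range(12):
                np.testing.assert_allclose(
                    D[i, j], jaccard_dissimilarity(occ[i], occ[j]))


class TestBetaSummary:
    def test_perfect_two_cluster_structure(self):
        occ = np.array([[1, 1, 0, 0]] * 3 + [[0, 0, 1, 1]] * 3)
        sev = np.array([0.0, 0, 0, 100, 100, 100])
        res = beta_summary(occ[None], sev)
        np.testing.assert_allclose(res.correlation, 1.0)
        assert res.class_means.loc["unchanged", "unchanged"] == 0.0
        assert res.class_means.loc["high", "high"] == 0.0
        assert res.class_means.loc["unchanged", "high"] == 1.0

    def test_identical_communities_flag_undefined_correlation(self):
        occ = np.ones((2, 6, 3), dtype=int)
        res = beta_summary(occ, np.array([0.0, 10, 30, 60, 80, 100]))
        assert np.isnan(res.correlation)
        assert np.nanmax(res.class_means.to_numpy()) == 0.0

    def test_matches_brute_force_oracle(self, rng):
        occ = rng.integers(0, 2, size=(10, 5))
        sev = rng.uniform(0, 100, size=10)
        res = beta_summary(occ[None], sev)
        _, _, r_bf, class_bf = brute_force_beta_summary(occ, sev)
        np.testing.assert_allclose(res.correlation, r_bf, atol=1e-12)
        for key, val in class_bf.items():
            pair = sorted(key)
            a, b = (pair[0], pair[-1])
            np.testing.assert_allclose(res.class_means.loc[a, b], val,
                                       atol=1e-12)

    def test_perfect_detection_matches_raw_data_diversity(self, rng):
        # p = 1 everywhere detected: occurrence draws equal the raw data
        n_periods, n_species = 8, 4
        z_true = rng.integers(0, 2, size=(n_periods, n_species))
        sev = rng.uniform(0, 100, n_periods)
        posts, hists = {}, {}
        for s in range(n_species):
            y = np.repeat(z_true[:, s], 2)
            hists[f"sp{s}"] = DetectionHistory(
                y=y, obs_period=np.repeat(np.arange(n_periods), 2),
                n_periods=n_periods)
            posts[f"sp{s}"] = fake_posterior(
                np.zeros((150, 6)),
                psi=np.full((1, 150, n_periods), 0.5),
                q_miss=np.full((1, 150, n_periods), 1e-12))
        rng2 = np.random.default_rng(5)
        occ = np.stack([
            draw_occurrence_matrix(posts, hists, d, rng2) for d in range(30)
        ])
        res_draws = beta_summary(occ, sev)
        res_raw = beta_summary(z_true[None], sev)
        np.testing.assert_allclose(res_draws.mean_dissimilarity,
                                   res_raw.mean_dissimilarity)
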