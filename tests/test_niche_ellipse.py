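import numpy as np
import pytest

from isoniche.niche_ellipse import (
    NichePosterior,
    compare_areas,
    ellipse_points,
    fit_bivariate_posterior,
    sea_b,
    sea_small_sample,
    standard_ellipse_area,
)


def _rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestAreaFormulas:
    @pytest.mark.parametrize(
        "sigma, expected",
        [
            (np.eye(2), np.pi),
            (np.diag([4.0, 1.0]), 2 * np.pi),  # semi-axes 2 and 1
            (np.array([[2.0, 1.0], [1.0, 2.0]]), np.pi * np.sqrt(3.0)),
        ],
    )
    def test_known_areas(self, sigma, expected):
        assert standard_ellipse_area(sigma) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("theta", [0.3, 1.1, 2.7])
    def test_rotation_invariance(self, theta):
        sigma = np.array([[3.0, 0.7], [0.7, 1.2]])
        r = _rot(theta)
        assert standard_ellipse_area(r @ sigma @ r.T) == pytest.approx(
            standard_ellipse_area(sigma), abs=1e-10
        )

    def test_scaling_data_by_c_scales_area_by_c_squared(self):
        sigma = np.array([[2.0, 0.5], [0.5, 1.0]])
        c = 3.0
        assert standard_ellipse_area(c**2 * sigma) == pytest.approx(
            c**2 * standard_ellipse_area(sigma)
        )

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError):
            standard_ellipse_area(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestSmallSampleCorrection:
    def test_n3_doubles_area(self):
        assert sea_small_sample(np.eye(2), 3) == pytest.approx(2 * np.pi)

    def test_identity_n12(self):
        assert sea_small_sample(np.eye(2), 12) == pytest.approx(1.1 * np.pi)

    def test_large_n_limit(self):
        assert sea_small_sample(np.eye(2), 10**6) == pytest.approx(
            np.pi, rel=1e-5
        )

    def test_n_below_3_rejected(self):
        with pytest.raises(ValueError):
            sea_small_sample(np.eye(2), 2)


class TestBivariatePosterior:
    def test_posterior_mean_consistency(self, rng):
        mu0, sigma0 = np.array([-14.0, 16.5]), np.array([[1.0, 0.3], [0.3, 0.8]])
        xy = rng.multivariate_normal(mu0, sigma0, size=2000)
        post = fit_bivariate_posterior(xy, ndraw=2000, seed=1)
        assert np.allclose(post.mu.mean(axis=0), mu0, atol=0.05)

    def test_seed_reproducibility(self, rng):
        xy = rng.standard_normal((50, 2))
        a = fit_bivariate_posterior(xy, ndraw=100, seed=5)
        b = fit_bivariate_posterior(xy, ndraw=100, seed=5)
        assert np.array_equal(a.mu, b.mu) and np.array_equal(a.sigma, b.sigma)

    def test_collinear_points_rejected(self):
        xy = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="rank"):
            fit_bivariate_posterior(xy, ndraw=10, seed=0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            fit_bivariate_posterior(np.zeros((2, 2)), ndraw=10, seed=0)


class TestSeaB:
    def test_constant_sigma_draws_give_constant_areas(self):
        sigma = np.tile(np.diag([4.0, 1.0]), (200, 1, 1))
        post = NichePosterior("g", np.zeros((200, 2)), sigma, n=10)
        res = sea_b(post)
        assert np.allclose(res.draws, 2 * np.pi)
        assert res.mean == pytest.approx(2 * np.pi)

    def test_posterior_area_matches_plugin_oracle(self, rng):
        sigma0 = np.array([[2.0, 0.6], [0.6, 1.5]])
        xy = rng.multivariate_normal([0, 0], sigma0, size=1000)
        post = fit_bivariate_posterior(xy, ndraw=3000, seed=2)
        res = sea_b(post)
        plugin = standard_ellipse_area(np.cov(xy.T))
        assert res.mean == pytest.approx(plugin, rel=0.05)
        assert res.hdi95.contains(plugin)

    def test_hdi_brackets_plugin_in_most_replicates(self, rng):
        sigma0 = np.array([[1.5, -0.4], [-0.4, 0.9]])
        hits = 0
        for rep in range(20):
            xy = rng.multivariate_normal([0, 0], sigma0, size=300)
            res = sea_b(fit_bivariate_posterior(xy, ndraw=1500, seed=rep))
            hits += res.hdi95.contains(standard_ellipse_area(np.cov(xy.T)))
        assert hits >= 18


class TestCompareAreas:
    def test_identical_posteriors_near_half(self, rng):
        draws = rng.gamma(5.0, 1.0, size=4000)
        res = compare_areas(draws, draws.copy(), seed=0)
        assert res.p_a_greater == pytest.approx(0.5, abs=0.02)

    def test_separated_areas_decisive(self, rng):
        a = rng.multivariate_normal([0, 0], np.eye(2), size=500)
        b = rng.multivariate_normal([0, 0], 4 * np.eye(2), size=500)
        ra = sea_b(fit_bivariate_posterior(a, ndraw=2000, seed=3))
        rb = sea_b(fit_bivariate_posterior(b, ndraw=2000, seed=4))
        res = compare_areas(rb, ra)
        assert res.p_a_greater > 0.99
        assert res.mean_diff > 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compare_areas(np.array([]), np.arange(10.0))


def test_ellipse_points_lie_on_unit_mahalanobis_contour():
    mu = np.array([1.0, -2.0])
    sigma = np.array([[2.0, 0.5], [0.5, 1.0]])
    pts = ellipse_points(mu, sigma, radius=1.0, npoints=64)
    d = pts - mu
    q = np.einsum("ij,ji->i", d, np.linalg.solve(sigma, d.T))
    assert np.allclose(q, 1.0, atol=1e-10)
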