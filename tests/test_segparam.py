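"""DTW distance, GP surrogate, expected improvement, and the BO loop."""

from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from lipwave.motion_sim import make_ground_truth_sentence
from lipwave.segparam import (
    BoConfig,
    dtw_distance,
    expected_improvement,
    gp_fit,
    gp_posterior,
    optimize_segmentation,
    _matern52_ard,
)


def brute_force_dtw(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive recursion over all monotone warping paths (tiny inputs)."""
    n, m = a.shape[0], b.shape[0]

    @lru_cache(maxsize=None)
    def cum(i, j):
        d = float(np.linalg.norm(a[i] - b[j]))
        if i == 0 and j == 0:
            return d
        opts = []
        if i > 0:
            opts.append(cum(i - 1, j))
        if j > 0:
            opts.append(cum(i, j - 1))
        if i > 0 and j > 0:
            opts.append(cum(i - 1, j - 1))
        return d + min(opts)

    return cum(n - 1, m - 1)


class TestDtw:
    def test_identical_sequences_zero(self, rng):
        x = rng.normal(size=(4, 30))
        r = dtw_distance(x, x)
        assert r.distance == 0.0 and r.normalized == 0.0

    def test_single_cell(self):
        a = np.array([[1.0], [0.0], [0.0], [0.0]])
        b = np.zeros((4, 1))
        r = dtw_distance(a, b)
        assert r.distance == pytest.approx(1.0)
        assert r.normalized == pytest.approx(0.5)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(60):
            n, m = rng.integers(1, 9, size=2)
            a = rng.normal(size=(n, 4))
            b = rng.normal(size=(m, 4))
            got = dtw_distance(a.T, b.T)
            assert got.distance == pytest.approx(brute_force_dtw(a, b), abs=1e-9)
            assert got.normalized == pytest.approx(got.distance / (n + m))

    def test_symmetry(self, rng):
        for _ in range(10):
            a = rng.normal(size=(4, 12))
            b = rng.normal(size=(4, 12))
            assert dtw_distance(a, b).distance == pytest.approx(
                dtw_distance(b, a).distance, abs=1e-9
            )

    def test_empty_and_mismatched_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance(np.zeros((4, 0)), np.zeros((4, 3)))
        with pytest.raises(ValueError):
            dtw_distance(np.zeros((3, 5)), np.zeros((4, 5)))


class TestGpSurrogate:
    def test_constant_observations(self):
        x = np.linspace(0, 1, 5)[:, None]
        y = np.full(5, 2.5)
        gp = gp_fit(x, y, seed=0, center=True)
        mu, var = gp_posterior(gp, np.array([[0.37]]))
        assert mu[0] == pytest.approx(2.5, abs=2 * np.sqrt(var[0]) + 1e-6)

    def test_three_point_posterior_matches_direct_linear_algebra(self):
        x = np.array([[0.1], [0.5], [0.9]])
        y = np.array([1.0, 0.2, 0.8])
        gp = gp_fit(x, y, seed=0)
        q = np.array([[0.3], [0.7]])
        mu, var = gp_posterior(gp, q)
        k = _matern52_ard(x, x, gp.lengthscales, gp.sigma_f)
        ks = _matern52_ard(x, q, gp.lengthscales, gp.sigma_f)
        kinv = np.linalg.inv(k + gp.sigma_n**2 * np.eye(3))
        assert np.allclose(mu, ks.T @ kinv @ y, atol=1e-8)
        assert np.allclose(
            var, gp.sigma_f**2 - np.diag(ks.T @ kinv @ ks), atol=1e-8
        )

    def test_interpolates_with_tiny_noise(self):
        x = np.array([[0.1], [0.5], [0.9]])
        y = np.array([1.0, 0.2, 0.8])
        gp = gp_fit(x, y, seed=0)
        mu, var = gp_posterior(gp, x)
        assert np.allclose(mu, y, atol=0.05)
        assert np.all(var >= 0)

    def test_prior_reversion_far_from_data(self):
        x = np.array([[0.0], [0.1]])
        y = np.array([0.4, 0.6])
        gp = gp_fit(x, y, seed=0, center=False)
        mu, var = gp_posterior(gp, np.array([[500.0]]))
        assert mu[0] == pytest.approx(0.0, abs=1e-6)  # zero prior mean
        assert var[0] == pytest.approx(gp.sigma_f**2, rel=1e-4)

    def test_duplicate_observation_never_increases_variance(self):
        x = np.array([[0.1], [0.5], [0.9]])
        y = np.array([1.0, 0.2, 0.8])
        gp1 = gp_fit(x, y, seed=0)
        _, v1 = gp_posterior(gp1, np.array([[0.5]]))
        from lipwave.segparam import GpSurrogate

        gp2 = GpSurrogate(
            x=np.vstack([x, [[0.5]]]), y=np.append(y, 0.2),
            lengthscales=gp1.lengthscales, sigma_f=gp1.sigma_f, sigma_n=gp1.sigma_n,
        )
        _, v2 = gp_posterior(gp2, np.array([[0.5]]))
        assert v2[0] <= v1[0] + 1e-12

    def test_variance_nonnegative_on_random_queries(self, rng):
        x = rng.uniform(size=(15, 4))
        y = rng.normal(size=15)
        gp = gp_fit(x, y, restarts=2, seed=0)
        _, var = gp_posterior(gp, rng.uniform(size=(1000, 4)))
        assert np.all(var >= 0)

    def test_cross_check_against_sklearn(self):
        """Independent GP implementation agrees at fixed hyperparameters."""
        sklearn = pytest.importorskip("sklearn")
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import Matern

        rng = np.random.default_rng(5)
        x = rng.uniform(size=(12, 2))
        y = rng.normal(size=12)
        ls = np.array([0.3, 0.7])
        sn = 0.1
        from lipwave.segparam import GpSurrogate

        mine = GpSurrogate(x=x, y=y, lengthscales=ls, sigma_f=1.0, sigma_n=sn)
        ref = GaussianProcessRegressor(
            kernel=Matern(length_scale=ls, nu=2.5), alpha=sn**2, optimizer=None
        ).fit(x, y)
        q = rng.uniform(size=(20, 2))
        mu_mine, var_mine = gp_posterior(mine, q)
        mu_ref, sd_ref = ref.predict(q, return_std=True)
        assert np.allclose(mu_mine, mu_ref, atol=1e-8)
        assert np.allclose(np.sqrt(var_mine), sd_ref, atol=1e-6)


class TestExpectedImprovement:
    def test_zero_sigma_limits(self):
        assert expected_improvement(np.array([1.0]), np.array([0.0]), 0.5)[0] == 0.0
        assert expected_improvement(np.array([0.2]), np.array([0.0]), 0.5)[0] == pytest.approx(0.3)

    def test_at_incumbent_equals_phi_zero(self):
        ei = expected_improvement(np.array([0.0]), np.array([1.0]), 0.0)
        assert ei[0] == pytest.approx(norm.pdf(0.0))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(mu=st.floats(-2, 2), s1=st.floats(0.01, 3), s2=st.floats(0.01, 3))
    def test_monotone_in_sigma_at_incumbent(self, mu, s1, s2):
        lo, hi = sorted((s1, s2))
        ei_lo = expected_improvement(np.array([mu]), np.array([lo]), mu)[0]
        ei_hi = expected_improvement(np.array([mu]), np.array([hi]), mu)[0]
        assert ei_hi >= ei_lo

    def test_matches_closed_form(self):
        mu, sigma, fmin = 0.3, 0.4, 0.5
        z = (fmin - mu) / sigma
        expected = (fmin - mu) * norm.cdf(z) + sigma * norm.pdf(z)
        assert expected_improvement(np.array([mu]), np.array([sigma]), fmin)[0] == pytest.approx(expected)


class TestOptimization:
    def _problem(self, word_bank, true=(0.2, 0.1)):
        wids = list(word_bank)
        sets = [word_bank[w] for w in wids]
        params = [true] * len(wids)
        actual = [
            make_ground_truth_sentence([word_bank[w][j] for w in wids], params, 0.0, seed=j)
            for j in range(len(sets[0]))
        ]
        return sets, actual

    def test_initial_design_size_and_feasibility(self, word_bank):
        sets, actual = self._problem(word_bank)
        cfg = BoConfig(budget=12, seed=0)
        _, trace = optimize_segmentation(sets, actual, cfg)
        n_eval = trace["x"].shape[0]
        assert cfg.initial_design <= n_eval <= 12
        pairs = trace["x"].reshape(n_eval, -1, 2)
        assert np.all(pairs >= 0)
        assert np.all(pairs.sum(axis=2) <= 1.0 + 1e-9)

    def test_running_minimum_non_increasing(self, word_bank):
        sets, actual = self._problem(word_bank)
        _, trace = optimize_segmentation(sets, actual, BoConfig(budget=14, seed=1))
        assert np.all(np.diff(trace["running_min"]) <= 1e-12)

    def test_recovers_known_parameters(self, word_bank):
        sets, actual = self._problem(word_bank)
        params, trace = optimize_segmentation(sets, actual, BoConfig(budget=80, seed=3))
        assert np.abs(params.vector - np.array([0.2, 0.1] * 3)).max() <= 0.05
        # the optimum beats the naive zero-parameter synthesis
        from lipwave.segparam import make_objective

        zero = make_objective(sets, actual)(np.zeros(6))
        assert trace["y"][trace["best_index"]] < zero

    def test_budget_below_design_rejected(self):
        with pytest.raises(ValueError):
            BoConfig(budget=4, initial_design=8)
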