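import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize

from fcmseg.fcm import (FCMConfig, defuzzify, fcm_objective,
                        initialize_centers, normalize_intensities, run_fcm,
                        update_centers, update_memberships)


def lagrangian_membership_oracle(x, centers, m):
    """Constrained numerical minimizer of the per-pixel FCM Lagrangian.

    For fixed centers the objective separates over pixels; each column of U is
    the minimizer of sum_k u_k^m c_k^2 subject to sum_k u_k = 1, u >= 0.
    Independent of the closed-form update it checks.
    """
    x = np.asarray(x, dtype=float).ravel()
    centers = np.asarray(centers, dtype=float)
    b = centers.size
    out = np.empty((b, x.size))
    for i, xi in enumerate(x):
        c2 = (xi - centers) ** 2

        def obj(u):
            return float((u ** m * c2).sum())

        res = minimize(obj, np.full(b, 1.0 / b), method="SLSQP",
                       bounds=[(0.0, 1.0)] * b,
                       constraints=[{"type": "eq",
                                     "fun": lambda u: u.sum() - 1.0}],
                       options={"ftol": 1e-14, "maxiter": 500})
        out[:, i] = res.x
    return out


class TestInitializeCenters:
    def test_quantile_init_hits_quartiles_for_two_clusters(self):
        x = np.linspace(0.0, 1.0, 101)
        v = initialize_centers(x, FCMConfig(n_clusters=2, init="quantile"))
        assert v == pytest.approx([0.25, 0.75])

    @pytest.mark.parametrize("init", ["random-pixels", "quantile", "kmeans-like"])
    def test_deterministic_given_seed(self, init, rng):
        x = rng.random((32, 32))
        cfg = FCMConfig(n_clusters=3, init=init, seed=4)
        assert np.array_equal(initialize_centers(x, cfg),
                              initialize_centers(x, cfg))

    def test_centers_are_distinct(self, rng):
        x = rng.choice([0.1, 0.5, 0.9], size=200)
        v = initialize_centers(x, FCMConfig(n_clusters=3, init="kmeans-like"))
        assert np.unique(v).size == 3

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            initialize_centers(np.full((16, 16), 0.5), FCMConfig(n_clusters=2))


class TestUpdateMemberships:
    def test_closed_form_example(self):
        mu = update_memberships(np.array([2.0]), np.array([0.0, 10.0]), m=2.0)
        assert mu[:, 0] == pytest.approx([16 / 17, 1 / 17])

    def test_pixel_on_center_gets_crisp_membership(self):
        mu = update_memberships(np.array([0.3]), np.array([0.3, 0.9]), m=2.0)
        assert mu[:, 0] == pytest.approx([1.0, 0.0])

    @pytest.mark.parametrize("m", [1.2, 2.0, 3.5])
    def test_equidistant_pixel_splits_evenly(self, m):
        mu = update_memberships(np.array([0.5]), np.array([0.0, 1.0]), m=m)
        assert mu[:, 0] == pytest.approx([0.5, 0.5])

    @given(st.integers(0, 2 ** 31 - 1))
    def test_columns_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(20)
        v = np.sort(rng.random(3))
        if np.unique(v).size < 3:
            return
        mu = update_memberships(x, v, m=2.0)
        assert np.allclose(mu.sum(axis=0), 1.0, atol=1e-9)
        assert mu.min() >= 0 and mu.max() <= 1

    def test_matches_constrained_lagrangian_minimizer(self, rng):
        """Closed form equals numerical stationary point of the Lagrangian."""
        for _ in range(5):
            x = rng.random(6)
            v = np.array([0.15, 0.85]) + rng.normal(0, 0.02, 2)
            mu = update_memberships(x, v, m=2.0)
            oracle = lagrangian_membership_oracle(x, v, m=2.0)
            assert np.abs(mu - oracle).max() < 1e-5


class TestUpdateCenters:
    def test_crisp_memberships_give_class_means(self):
        x = np.array([1.0, 2.0, 9.0, 11.0])
        mu = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=float)
        assert update_centers(x, mu, m=2.0) == pytest.approx([1.5, 10.0])

    def test_uniform_memberships_give_global_mean(self, rng):
        x = rng.random(50)
        mu = np.full((3, 50), 1 / 3)
        assert update_centers(x, mu, m=2.0) == pytest.approx([x.mean()] * 3)

    def test_weighted_mean_hand_example(self):
        x = np.array([0.0, 10.0])
        mu = np.array([[0.8, 0.2], [0.2, 0.8]])
        v = update_centers(x, mu, m=2.0)
        assert v[0] == pytest.approx((0.64 * 0 + 0.04 * 10) / (0.64 + 0.04))

    def test_all_zero_class_rejected(self):
        mu = np.array([[1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            update_centers(np.array([1.0, 2.0]), mu, m=2.0)

    def test_matches_direct_weighted_average(self, rng):
        """Independent loop-based oracle to 1e-10 on random small instances."""
        for _ in range(10):
            n, b, m = 12, 3, 1.7
            x = rng.random(n)
            mu = rng.random((b, n))
            mu /= mu.sum(axis=0)
            v = update_centers(x, mu, m=m)
            for k in range(b):
                num = sum(mu[k, i] ** m * x[i] for i in range(n))
                den = sum(mu[k, i] ** m for i in range(n))
                assert abs(v[k] - num / den) < 1e-10


class TestObjective:
    def test_hand_summed_example(self):
        x = np.array([1.0, 2.0, 9.0, 11.0])
        mu = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=float)
        v = np.array([1.5, 10.0])
        assert fcm_objective(x, mu, v, m=2.0) == pytest.approx(2.5)

    def test_zero_when_pixels_sit_on_centers(self):
        x = np.array([0.2, 0.8])
        mu = np.eye(2)
        assert fcm_objective(x, mu, np.array([0.2, 0.8]), m=2.0) == 0.0

    def test_quadratic_homogeneity(self, rng):
        x = rng.random(30)
        v = np.array([0.2, 0.7])
        mu = update_memberships(x, v, m=2.0)
        g1 = fcm_objective(x, mu, v, m=2.0)
        g2 = fcm_objective(2 * x, mu, 2 * v, m=2.0)
        assert g2 == pytest.approx(4 * g1)


class TestRunFCM:
    def test_separated_groups_recovered_exactly(self, rng):
        truth = np.repeat([0, 1], 100)
        x = np.where(truth == 0, rng.normal(-5, 0.1, 200),
                     rng.normal(5, 0.1, 200))
        res = run_fcm(x, FCMConfig(n_clusters=2))
        labels = res.labels
        if labels[0] != truth[0]:
            labels = 1 - labels
        assert np.array_equal(labels, truth)

    def test_noiseless_phantom_centers_match_class_means(self, small_phantom):
        res = run_fcm(small_phantom.image,
                      FCMConfig(n_clusters=4, tol=1e-6))
        assert res.converged
        expected = normalize_intensities(
            np.asarray(small_phantom.spec.class_means))
        assert np.abs(np.sort(res.centers) - expected).max() < 1e-3

    def test_objective_trace_non_increasing(self, small_phantom, rng):
        noisy = small_phantom.image + rng.normal(0, 0.1, (64, 64))
        res = run_fcm(noisy, FCMConfig(n_clusters=4))
        trace = res.objective_trace
        assert all(b <= a + 1e-8 for a, b in zip(trace, trace[1:]))

    def test_iteration_cap_contract(self, small_phantom, rng):
        noisy = np.clip(small_phantom.image + rng.normal(0, 0.1, (64, 64)),
                        0, 1)
        res = run_fcm(noisy, FCMConfig(n_clusters=4, max_iter=1, tol=1e-12))
        assert res.n_iter == 1 and not res.converged
        assert len(res.objective_trace) == 2  # initial + one update

    def test_deterministic_given_seed(self, small_phantom):
        cfg = FCMConfig(n_clusters=4, init="random-pixels", seed=3)
        a = run_fcm(small_phantom.image, cfg)
        b = run_fcm(small_phantom.image, cfg)
        assert np.array_equal(a.memberships, b.memberships)
        assert np.array_equal(a.centers, b.centers)

    def test_permutation_equivariance(self, small_phantom, rng):
        """Permuting initial centers permutes output classes identically."""
        noisy = np.clip(small_phantom.image + rng.normal(0, 0.05, (64, 64)),
                        0, 1)
        cfg = FCMConfig(n_clusters=4)
        v0 = np.array([0.1, 0.4, 0.6, 0.9])
        perm = np.array([2, 0, 3, 1])
        a = run_fcm(noisy, cfg, initial_centers=v0)
        b = run_fcm(noisy, cfg, initial_centers=v0[perm])
        assert np.allclose(a.centers, b.centers[np.argsort(perm)])
        assert np.allclose(a.memberships, b.memberships[np.argsort(perm)])


class TestDefuzzify:
    def test_argmax_and_tie_break(self):
        mu = np.array([[0.9, 0.5, 0.1], [0.1, 0.5, 0.9]])
        assert defuzzify(mu).tolist() == [0, 0, 1]

    def test_identity_on_crisp_input(self, rng):
        labels = rng.integers(0, 3, 40)
        mu = np.zeros((3, 40))
        mu[labels, np.arange(40)] = 1.0
        assert np.array_equal(defuzzify(mu), labels)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"fuzzifier": 1.0}, {"tol": 0.0}, {"max_iter": 0},
        {"init": "bogus"}, {"n_clusters": 1},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FCMConfig(**kwargs)
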