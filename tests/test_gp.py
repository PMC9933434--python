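"""Kernels and exact-GP algebra against independent dense oracles."""

import numpy as np
import pytest

from exciham import (
    CompositeShiftKernel,
    GaussianProcess,
    GPResults,
    LinearKernel,
    MaternKernel,
    ShiftFeatures,
    composite_shift_kernel,
    fit_gp,
    linear_kernel,
    matern_kernel,
    predict_gp,
)
from exciham.gp import JITTER


def random_shift_features(n, n_cm=8, n_pot=5, seed=0):
    rng = np.random.default_rng(seed)
    return ShiftFeatures(cm=rng.normal(0, 2, (n, n_cm)), pot=rng.normal(0, 0.1, (n, n_pot)))


class TestMatern:
    def test_value_at_zero_is_variance(self):
        assert matern_kernel(0.0, sigma=1.7, lengthscale=2.0) == pytest.approx(1.7**2)

    def test_decay_limit(self):
        v = matern_kernel(100.0 * 3.0, sigma=2.0, lengthscale=3.0)
        assert v < 1e-10 * 2.0**2

    def test_strictly_decreasing(self):
        d = np.linspace(0, 10, 50)
        v = matern_kernel(d, 1.0, 1.0)
        assert np.all(np.diff(v) < 0)

    def test_gram_psd(self, rng):
        X = rng.normal(size=(20, 4))
        K = MaternKernel(sigma=1.3, lengthscale=0.8)(X)
        np.testing.assert_allclose(K, K.T, atol=1e-15)
        assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            matern_kernel(-1.0, 1.0, 1.0)


class TestLinearKernel:
    def test_examples(self):
        assert linear_kernel([3.0, 4.0], [3.0, 4.0], sigma1=1.0) == pytest.approx(25.0)
        assert linear_kernel([1.0, 2.0], [0.0, 0.0]) == 0.0

    def test_gp_posterior_matches_ridge_regression(self, rng):
        """A linear-kernel GP is ridge regression on the potential features."""
        n, p = 30, 6
        Phi = rng.normal(0, 0.3, (n, p))
        y = Phi @ rng.normal(size=p) + 0.01 * rng.normal(size=n)
        s1, noise = 0.7, 1e-4
        res = fit_gp(Phi, y, LinearKernel(sigma1=s1), noise_variance=noise,
                     prior_mean_mode="zero")
        # primal closed form: w = (Phi^T Phi + (noise/s1^2) I)^-1 Phi^T y
        w = np.linalg.solve(
            Phi.T @ Phi + (noise / s1**2) * np.eye(p), Phi.T @ y
        )
        Xs = rng.normal(0, 0.3, (7, p))
        np.testing.assert_allclose(res.predict(Xs), Xs @ w, rtol=0, atol=1e-8)


class TestCompositeShiftKernel:
    def test_zero_potential_forces_zero(self, rng):
        cm1, cm2 = rng.normal(size=4), rng.normal(size=4)
        val = composite_shift_kernel(
            (cm1, np.zeros(3)), (cm2, rng.normal(size=3)), 1.0, 2.0, 1.5
        )
        assert val == 0.0

    def test_identical_inputs(self, rng):
        cm, pot = rng.normal(size=4), rng.normal(size=3)
        val = composite_shift_kernel((cm, pot), (cm, pot), 1.2, 0.8, 2.0)
        assert val == pytest.approx((1.2**2 + 0.8**2) * pot @ pot, rel=1e-12)

    def test_gram_psd(self):
        X = random_shift_features(30, seed=5)
        K = CompositeShiftKernel(0.9, 1.1, 2.0)(X)
        np.testing.assert_allclose(K, K.T, atol=1e-14)
        assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_requires_both_descriptors(self):
        with pytest.raises(TypeError):
            CompositeShiftKernel()(np.zeros((3, 4)))


def dense_posterior(kernel, X, y, mu, noise, Xs):
    """Independent textbook implementation with explicit matrix inverse."""
    K = kernel(X) + (noise + JITTER) * np.eye(len(y))
    Kinv = np.linalg.inv(K)
    ks = kernel(Xs, X)
    mean = mu + ks @ Kinv @ (y - mu)
    var = kernel.diag(Xs) - np.einsum("ij,jk,ik->i", ks, Kinv, ks)
    return mean, var


class TestFitPredict:
    def test_single_point_scalar_solve(self):
        X = np.array([[1.0, 2.0]])
        y = np.array([3.0])
        k = MaternKernel(sigma=2.0, lengthscale=1.0)
        res = fit_gp(X, y, k, noise_variance=0.0, prior_mean_mode="zero")
        assert res.alpha_[0] == pytest.approx(3.0 / (4.0 + JITTER), rel=1e-10)

    def test_alpha_matches_dense_inverse(self, rng):
        X = rng.normal(size=(3, 2))
        y = rng.normal(size=3)
        k = MaternKernel(1.0, 1.0)
        res = fit_gp(X, y, k, noise_variance=0.01)
        mu = y.mean()
        expected = np.linalg.inv(k(X) + (0.01 + JITTER) * np.eye(3)) @ (y - mu)
        np.testing.assert_allclose(res.alpha_, expected, rtol=0, atol=1e-10)

    def test_constant_targets_give_zero_alpha(self, rng):
        X = rng.normal(size=(8, 3))
        res = fit_gp(X, np.full(8, 2.1), MaternKernel(), noise_variance=0.1,
                     prior_mean_mode="mean_of_targets")
        np.testing.assert_allclose(res.alpha_, 0.0, atol=1e-14)

    def test_exact_interpolation(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        res = fit_gp(X, y, MaternKernel(1.0, 2.0), noise_variance=0.0)
        mean, var = predict_gp(res, X)
        np.testing.assert_allclose(mean, y, rtol=0, atol=1e-8)
        assert np.all(var <= 1e-8)

    def test_far_point_recovers_prior(self, rng):
        X = rng.normal(size=(10, 2))
        y = 2.0 + rng.normal(size=10)
        k = MaternKernel(sigma=0.5, lengthscale=1.0)
        res = fit_gp(X, y, k, noise_variance=1e-4)
        mean, var = predict_gp(res, np.array([[500.0, 500.0]]))
        assert mean[0] == pytest.approx(y.mean(), abs=1e-8)
        assert var[0] == pytest.approx(0.25, rel=1e-8)

    @pytest.mark.parametrize("kernel_factory,data_factory", [
        (lambda: MaternKernel(1.2, 0.9), lambda rng: rng.normal(size=(12, 3))),
        (lambda: CompositeShiftKernel(0.8, 1.1, 2.0),
         lambda rng: random_shift_features(12, seed=3)),
    ])
    def test_posterior_matches_dense_oracle(self, kernel_factory, data_factory, rng):
        X = data_factory(rng)
        y = rng.normal(size=12)
        k = kernel_factory()
        res = fit_gp(X, y, k, noise_variance=1e-3, prior_mean_mode="zero")
        Xs = data_factory(np.random.default_rng(99))
        mean, var = predict_gp(res, Xs)
        dmean, dvar = dense_posterior(k, X, y, 0.0, 1e-3, Xs)
        np.testing.assert_allclose(mean, dmean, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(var, np.clip(dvar, 0, None), rtol=1e-8, atol=1e-12)

    def test_variance_bounded_by_prior(self, rng):
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        k = MaternKernel(1.5, 1.0)
        res = fit_gp(X, y, k, noise_variance=1e-4)
        _, var = predict_gp(res, rng.normal(size=(30, 2)))
        assert np.all(var >= 0)
        assert np.all(var <= 1.5**2 + 1e-12)

    def test_prediction_invariant_to_training_order(self, rng):
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        perm = rng.permutation(25)
        k = MaternKernel(1.0, 1.3)
        a = fit_gp(X, y, k, noise_variance=1e-4)
        b = fit_gp(X[perm], y[perm], k, noise_variance=1e-4)
        Xs = rng.normal(size=(6, 3))
        np.testing.assert_allclose(a.predict(Xs), b.predict(Xs), rtol=0, atol=1e-10)


class TestLML:
    def test_matches_independent_closed_form(self, rng):
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        k = MaternKernel(1.1, 0.7)
        noise = 0.05
        res = fit_gp(X, y, k, noise_variance=noise, prior_mean_mode="zero")
        K = k(X) + (noise + JITTER) * np.eye(5)
        sign, logdet = np.linalg.slogdet(K)
        expected = (
            -0.5 * y @ np.linalg.inv(K) @ y - 0.5 * logdet - 2.5 * np.log(2 * np.pi)
        )
        assert sign > 0
        assert res.loglike() == pytest.approx(expected, rel=1e-10)

    def test_optimum_beats_random_draws(self, rng):
        X = rng.normal(size=(40, 2))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=40)
        model = GaussianProcess(X, y, MaternKernel(), prior_mean="zero")
        res = model.fit(restarts=3, seed=0)
        best = res.loglike()
        for _ in range(10):
            theta = rng.uniform(np.log(0.05), np.log(20.0), size=2)
            ll = model.loglike(MaternKernel().with_theta(theta), res.noise_variance_)
            assert ll <= best + 1e-6

    def test_lengthscale_recovery_from_simulated_gp(self):
        rng = np.random.default_rng(42)
        n, true_l, true_s = 200, 0.5, 1.0
        X = rng.uniform(-2, 2, size=(n, 2))
        K = MaternKernel(true_s, true_l)(X) + 1e-8 * np.eye(n)
        y = np.linalg.cholesky(K) @ rng.normal(size=n)
        res = GaussianProcess(X, y, MaternKernel(), prior_mean="zero").fit(
            restarts=3, seed=1
        )
        assert true_l / 2 <= res.kernel_.lengthscale <= true_l * 2

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        r1 = GaussianProcess(X, y, MaternKernel()).fit(restarts=3, seed=5)
        r2 = GaussianProcess(X, y, MaternKernel()).fit(restarts=3, seed=5)
        assert r1.kernel_.params() == r2.kernel_.params()
        assert r1.noise_variance_ == r2.noise_variance_


class TestSerialization:
    @pytest.mark.parametrize("use_shift", [False, True])
    def test_roundtrip_identical_predictions(self, tmp_path, rng, use_shift):
        if use_shift:
            X = random_shift_features(15, seed=8)
            Xs = random_shift_features(5, seed=9)
            k = CompositeShiftKernel(0.9, 1.2, 1.7)
        else:
            X = rng.normal(size=(15, 3))
            Xs = rng.normal(size=(5, 3))
            k = MaternKernel(1.1, 0.6)
        y = rng.normal(size=15)
        res = fit_gp(X, y, k, noise_variance=1e-4, prior_mean_mode="zero")
        res.save(tmp_path / "model.json")
        loaded = GPResults.load(tmp_path / "model.json")
        m0, v0 = res.predict(Xs, return_var=True)
        m1, v1 = loaded.predict(Xs, return_var=True)
        np.testing.assert_allclose(m1, m0, rtol=0, atol=1e-12)
        np.testing.assert_allclose(v1, v0, rtol=0, atol=1e-12)

    def test_schema_version_enforced(self, tmp_path, rng):
        res = fit_gp(rng.normal(size=(5, 2)), rng.normal(size=5), MaternKernel())
        path = tmp_path / "m.json"
        res.save(path)
        import json

        data = json.loads(path.read_text())
        data["schema_version"] = 999
        path.write_text(json.dumps(data))
        with pytest.raises(ValueError, match="schema"):
            GPResults.load(path)
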