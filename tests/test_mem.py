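import numpy as np
import pytest
from scipy.special import expit

from memdot.mem import (
    MemDual,
    ParcelModel,
    free_energy,
    init_prior,
    maximize_dual,
    mem_estimate,
    solve_mem,
)
from memdot.parcellation import Parcellation
from memdot.preprocess import NoiseModel


def toy_model(alphas, sigmas, eta=1.0):
    """Parcel model with scalar (single-vertex) parcels."""
    K = len(alphas)
    labels = np.arange(K)
    parc = Parcellation(labels=labels, K=K, seed_vertices=labels.copy())
    return ParcelModel(
        parcellation=parc,
        alpha=np.asarray(alphas, float),
        base=[np.array([[s]]) for s in sigmas],
        eta=np.full((K, 1), eta),
        omega1=0.0,
        omega2=0.0,
    )


def block_model(alphas, sigma_blocks, eta=1.0):
    sizes = [s.shape[0] for s in sigma_blocks]
    labels = np.concatenate([[k] * n for k, n in enumerate(sizes)])
    parc = Parcellation(labels=labels, K=len(sizes), seed_vertices=np.array(
        [int(np.flatnonzero(labels == k)[0]) for k in range(len(sizes))]))
    return ParcelModel(
        parcellation=parc,
        alpha=np.asarray(alphas, float),
        base=list(sigma_blocks),
        eta=np.full((len(sizes), 1), eta),
        omega1=0.0,
        omega2=0.0,
    )


def rand_psd(rng, n, scale=1.0):
    M = rng.normal(size=(n, n))
    return scale * (M @ M.T / n + 0.5 * np.eye(n))


def noise_eye(p, scale=1.0):
    return NoiseModel(covariance=scale * np.eye(p), precision=np.eye(p) / scale)


class TestFreeEnergy:
    def test_zero_point(self):
        model = toy_model([0.3, 0.7], [1.0, 2.0])
        val, grad = free_energy(np.zeros(2), model)
        assert val == pytest.approx(0.0, abs=1e-14)
        np.testing.assert_allclose(grad, 0.0, atol=1e-14)

    def test_alpha_to_one_gaussian_limit(self):
        sigma = 1.7
        model = toy_model([1 - 1e-12], [sigma])
        xi = np.array([0.8])
        val, grad = free_energy(xi, model)
        assert val == pytest.approx(0.5 * sigma * 0.8**2, rel=1e-6)
        assert grad[0] == pytest.approx(sigma * 0.8, rel=1e-6)

    def test_scalar_hand_values(self):
        # alpha=0.5, Sigma=1, xi=1: F = log(0.5 + 0.5 e^{1/2}),
        # gradient = sigmoid(1/2) * 1
        model = toy_model([0.5], [1.0])
        val, grad = free_energy(np.array([1.0]), model)
        assert val == pytest.approx(np.log(0.5 + 0.5 * np.exp(0.5)), abs=1e-10)
        assert val == pytest.approx(0.2809, abs=2e-4)
        assert grad[0] == pytest.approx(np.exp(0.5) / (1 + np.exp(0.5)), abs=1e-10)
        assert grad[0] == pytest.approx(0.6225, abs=2e-4)

    def test_gradient_matches_numerical(self, rng):
        blocks = [rand_psd(rng, 3), rand_psd(rng, 2), rand_psd(rng, 4)]
        model = block_model([0.2, 0.5, 0.9], blocks)
        xi = rng.normal(size=9) * 0.5
        _, grad = free_energy(xi, model)
        eps = 1e-6
        for i in range(9):
            e = np.zeros(9)
            e[i] = eps
            f_plus, _ = free_energy(xi + e, model)
            f_minus, _ = free_energy(xi - e, model)
            num = (f_plus - f_minus) / (2 * eps)
            assert grad[i] == pytest.approx(num, abs=1e-5)

    def test_overflow_safe_for_large_xi(self):
        model = toy_model([0.5], [1.0])
        val, grad = free_energy(np.array([100.0]), model)
        assert np.isfinite(val) and np.isfinite(grad[0])
        assert grad[0] == pytest.approx(100.0, rel=1e-6)  # gamma -> 1


class TestMaximizeDual:
    def test_zero_data_gives_zero_dual(self, rng):
        p, q = 4, 6
        A = rng.normal(size=(p, q))
        blocks = [rand_psd(rng, 3), rand_psd(rng, 3)]
        model = block_model([0.4, 0.6], blocks)
        dual = maximize_dual(np.zeros(p), A, noise_eye(p), model)
        assert dual.converged
        np.testing.assert_allclose(dual.lambda_dual, 0.0, atol=1e-6)

    def test_gaussian_limit_matches_linear_solve(self, rng):
        p, q = 5, 7
        A = rng.normal(size=(p, q))
        blocks = [rand_psd(rng, 4), rand_psd(rng, 3)]
        model = block_model([1 - 1e-13, 1 - 1e-13], blocks)
        y = rng.normal(size=p)
        noise = noise_eye(p, scale=0.5)
        dual = maximize_dual(y, A, noise, model, tol=1e-10)
        Sigma = np.zeros((q, q))
        Sigma[:4, :4] = blocks[0]
        Sigma[4:, 4:] = blocks[1]
        lam_oracle = np.linalg.solve(A @ Sigma @ A.T + noise.covariance, y)
        np.testing.assert_allclose(dual.lambda_dual, lam_oracle, rtol=1e-4, atol=1e-6)

    def test_one_channel_matches_grid_search(self, rng):
        A = np.array([[1.3]])
        model = toy_model([0.4], [0.8])
        y = np.array([0.9])
        noise = noise_eye(1, scale=0.3)
        dual = maximize_dual(y, A, noise, model, tol=1e-10)

        def D(lam):
            xi = A.T @ np.array([lam])
            f, _ = free_energy(xi, model)
            return lam * y[0] - f - 0.5 * 0.3 * lam**2

        grid = np.linspace(-5, 5, 200001)
        lam_star = grid[np.argmax([D(l) for l in grid])]
        assert dual.lambda_dual[0] == pytest.approx(lam_star, abs=1e-4)

    def test_concavity_along_random_segments(self, rng):
        p, q = 4, 5
        A = rng.normal(size=(p, q))
        model = block_model([0.3, 0.8], [rand_psd(rng, 2), rand_psd(rng, 3)])
        noise = noise_eye(p)

        def D(lam):
            xi = A.T @ lam
            f, _ = free_energy(xi, model)
            return float(lam @ np.ones(p) * 0) + float(lam @ rng_y) - f - 0.5 * float(lam @ lam)

        rng_y = rng.normal(size=p)
        for _ in range(10):
            a = rng.normal(size=p)
            b = rng.normal(size=p)
            ts = np.linspace(0, 1, 9)
            vals = np.array([D(a + t * (b - a)) for t in ts])
            second_diff = vals[:-2] - 2 * vals[1:-1] + vals[2:]
            assert np.all(second_diff <= 1e-8 * max(1.0, np.abs(vals).max()))


class TestMemEstimate:
    def test_zero_dual_zero_mean_gives_zero_map(self, rng):
        p, q = 3, 4
        A = rng.normal(size=(p, q))
        model = block_model([0.5, 0.5], [rand_psd(rng, 2), rand_psd(rng, 2)])
        dual = MemDual(lambda_dual=np.zeros(p), converged=True, dual_value=0.0, grad_norm=0.0)
        x = mem_estimate(dual, A, model)
        np.testing.assert_array_equal(x, 0.0)

    def test_gaussian_limit_equals_map_estimator(self, rng):
        p, q = 6, 10
        A = rng.normal(size=(p, q))
        blocks = [rand_psd(rng, 5), rand_psd(rng, 5)]
        model = block_model([1 - 1e-13, 1 - 1e-13], blocks)
        y = rng.normal(size=p)
        noise = noise_eye(p, scale=0.4)
        dual = maximize_dual(y, A, noise, model, tol=1e-12)
        x = mem_estimate(dual, A, model)
        Sigma = np.zeros((q, q))
        Sigma[:5, :5] = blocks[0]
        Sigma[5:, 5:] = blocks[1]
        oracle = Sigma @ A.T @ np.linalg.solve(A @ Sigma @ A.T + noise.covariance, y)
        np.testing.assert_allclose(x, oracle, rtol=1e-4, atol=1e-6)

    def test_switch_off_inactive_orthogonal_parcel(self, rng):
        # channels see parcel 0 only; parcel 1's columns are zero and its
        # activation prior is tiny -> its amplitudes must be exactly 0
        p = 4
        A = np.hstack([rng.normal(size=(p, 3)), np.zeros((p, 3))])
        blocks = [rand_psd(rng, 3), rand_psd(rng, 3)]
        model = block_model([0.9, 0.01], blocks)
        x_true = rng.normal(size=3)
        y = A[:, :3] @ x_true
        dual = maximize_dual(y, A, noise_eye(p, 1e-4), model, tol=1e-10)
        x = mem_estimate(dual, A, model)
        assert np.all(x[3:] == 0.0)
        outside = np.sum(x[3:] ** 2)
        total = np.sum(x**2)
        assert outside < 0.05 * total

    def test_duality_residual_identity(self, rng):
        # at the maximizer: Y - A x_hat = Cov lambda*
        p, q = 5, 8
        A = rng.normal(size=(p, q))
        model = block_model([0.6, 0.7], [rand_psd(rng, 4), rand_psd(rng, 4)])
        y = rng.normal(size=p)
        noise = noise_eye(p, scale=0.2)
        dual = maximize_dual(y, A, noise, model, tol=1e-12)
        x = mem_estimate(dual, A, model)
        np.testing.assert_allclose(
            y - A @ x, noise.covariance @ dual.lambda_dual, atol=1e-5
        )


class TestSolveMem:
    def test_identical_time_samples_give_identical_maps(self, phantom):
        cfg, mesh, montage, sens = phantom
        from memdot.mesh import field_of_view
        from memdot.parcellation import grow_parcels, msp_scores

        rng = np.random.default_rng(1)
        fov = field_of_view(sens, cfg.fov_threshold)
        A = sens.matrices[830.0].copy()
        A[:, ~fov] = 0.0
        p = A.shape[0]
        y0 = rng.normal(size=p) * 1e-4
        Y = np.column_stack([y0, y0])
        noise = NoiseModel(covariance=1e-8 * np.eye(p), precision=1e8 * np.eye(p))
        scores = msp_scores(np.column_stack([y0, -0.5 * y0, 2 * y0]), A)
        parcels = grow_parcels(mesh, scores, fov_mask=fov)
        cmap = solve_mem(Y, A, noise, parcels, mesh=mesh, alpha_scores=scores)
        np.testing.assert_allclose(cmap.amplitudes[:, 0], cmap.amplitudes[:, 1], atol=1e-8)
        assert cmap.method_tag == "MEM(0.3,0.5)"

    def test_prior_initialization_contract(self, phantom, rng):
        cfg, mesh, montage, sens = phantom
        from memdot.mesh import field_of_view
        from memdot.parcellation import grow_parcels, msp_scores

        fov = field_of_view(sens, cfg.fov_threshold)
        A = sens.matrices[830.0].copy()
        A[:, ~fov] = 0.0
        p = A.shape[0]
        Y = rng.normal(size=(p, 6)) * 1e-4
        noise = NoiseModel(covariance=1e-8 * np.eye(p), precision=1e8 * np.eye(p))
        scores = msp_scores(Y, A)
        parcels = grow_parcels(mesh, scores, fov_mask=fov)
        model = init_prior(Y, A, noise, parcels, omega1=0.3, omega2=0.5,
                           alpha_scores=scores, mesh=mesh)
        assert np.all((model.alpha >= 0.05) & (model.alpha <= 0.95))
        assert model.eta.shape == (parcels.K, 6)
        assert np.all(model.eta > 0)
        for k in range(model.K):
            B = model.base[k]
            np.testing.assert_allclose(B, B.T, atol=1e-10)
            ev = np.linalg.eigvalsh(B)
            assert ev.min() > -1e-10

    def test_local_normalization_scale_invariance(self, phantom, rng):
        cfg, mesh, montage, sens = phantom
        from memdot.mesh import field_of_view
        from memdot.parcellation import grow_parcels, msp_scores

        fov = field_of_view(sens, cfg.fov_threshold)
        A = sens.matrices[830.0].copy()
        A[:, ~fov] = 0.0
        p = A.shape[0]
        Y = rng.normal(size=(p, 4)) * 1e-4
        noise = NoiseModel(covariance=1e-8 * np.eye(p), precision=1e8 * np.eye(p))
        scores = msp_scores(Y, A)
        parcels = grow_parcels(mesh, scores, fov_mask=fov)
        m1 = init_prior(Y, A, noise, parcels, alpha_scores=scores, mesh=mesh)
        m2 = init_prior(7.0 * Y, A, noise, parcels, alpha_scores=scores, mesh=mesh)
        np.testing.assert_allclose(m1.eta, m2.eta, rtol=1e-8)
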