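import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from robustblup import (
    DispersionParams,
    KinshipMatrix,
    ModelData,
    effective_shrinkage,
    fit_gblup,
    fit_lmap,
    fit_tmap,
    fit_tmap_newton,
    lmap_weights,
    posterior_covariance,
    solve_weighted_mme,
    tmap_weights,
)

SCALAR_K = KinshipMatrix(["a"], np.array([[1.0]]))
# K=1, Z=1, y=2, nu=4, tau_e2=1, sigma_g2=2 -> lambda''=0.4; the stationary
# point of the t log-posterior solved numerically to high precision
SCALAR_TMAP_PARAMS = DispersionParams(sigma_g2=2.0, sigma_e2=2.0, nu=4.0)
SCALAR_TMAP_GHAT = 1.39179708946428  # frozen root of the stationarity cubic


def random_instance(seed, n=6, with_W=True, reps=True):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2 * n))
    K = KinshipMatrix([f"i{i}" for i in range(n)],
                      X @ X.T / (2 * n) + 0.3 * np.eye(n))
    W = np.c_[np.ones(n), rng.normal(size=n)] if with_W else None
    nc = rng.integers(1, 4, size=n).astype(float) if reps else None
    y = rng.normal(size=n)
    return ModelData(y=y, K=K, W=W, n_counts=nc)


class TestWeightedMme:
    def test_two_by_two_hand_solution(self):
        K = KinshipMatrix(["a", "b"], np.array([[1, 0.5], [0.5, 1]]))
        data = ModelData(y=np.array([1.0, -1.0]), K=K)
        _, g = solve_weighted_mme(data, np.ones(2), 1.0)
        np.testing.assert_allclose(g, [1 / 3, -1 / 3], atol=1e-12)

    def test_vanishing_penalty_recovers_data(self, small_K):
        y = np.arange(10, dtype=float) - 4.5
        data = ModelData(y=y, K=small_K)
        _, g = solve_weighted_mme(data, np.ones(10), 1e-12)
        np.testing.assert_allclose(g, y, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equals_covariance_form_blup(self, seed):
        """MME solution must agree with the closed-form GLS/BLUP
        expressions alpha = (W'V^-1 W)^-1 W'V^-1 y and
        g = sigma_g2 K Z' V^-1 (y - W alpha)."""
        data = random_instance(seed)
        params = DispersionParams(0.5, 1.2)
        a, g = solve_weighted_mme(data, data.n_counts, params.lam)
        V = (data.K.values * params.sigma_g2
             + np.diag(params.sigma_e2 / data.n_counts))
        Vi = np.linalg.inv(V)
        a_ref = np.linalg.solve(data.W.T @ Vi @ data.W, data.W.T @ Vi @ data.y)
        g_ref = params.sigma_g2 * data.K.values @ Vi @ (data.y - data.W @ a_ref)
        np.testing.assert_allclose(a, a_ref, atol=1e-10)
        np.testing.assert_allclose(g, g_ref, atol=1e-10)

    def test_nonpositive_weight_rejected(self, small_K):
        data = ModelData(y=np.zeros(10), K=small_K)
        with pytest.raises(ValueError):
            solve_weighted_mme(data, np.zeros(10), 1.0)


class TestGblup:
    def test_identity_kinship_halves_data(self):
        K = KinshipMatrix(list("abcd"), np.eye(4))
        y = np.array([3.0, -1.0, 2.0, 0.5])
        fit = fit_gblup(ModelData(y=y, K=K), DispersionParams(1.0, 1.0))
        np.testing.assert_allclose(fit.g, y / 2, atol=1e-12)
        np.testing.assert_allclose(fit.weights, np.ones(4))

    def test_total_shrinkage_with_large_lambda(self, clean_model):
        norms = [
            np.linalg.norm(fit_gblup(
                clean_model, DispersionParams(1.0, lam)).g)
            for lam in (1.0, 10.0, 100.0, 1e4)
        ]
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-2 * norms[0]

    def test_replicated_records_use_n_weights(self):
        data = random_instance(11, with_W=False)
        params = DispersionParams(0.8, 0.9)
        fit = fit_gblup(data, params)
        N = np.diag(data.n_counts)
        g_ref = np.linalg.solve(
            N + params.lam * np.linalg.inv(data.K.values), N @ data.y)
        np.testing.assert_allclose(fit.g, g_ref, atol=1e-10)


class TestTmapWeights:
    def test_zero_residual_gives_full_weight(self):
        d = tmap_weights(np.zeros(3), np.array([1.0, 2, 5]), 1.0, 4.0)
        np.testing.assert_allclose(d, [1, 2, 5])

    def test_hand_value(self):
        d = tmap_weights(np.array([2.0]), np.array([1.0]), 1.0, 4.0)
        assert d[0] == pytest.approx(0.5)

    def test_huge_nu_recovers_gaussian_weights(self):
        d = tmap_weights(np.array([1.0, -3.0]), np.array([2.0, 4.0]),
                         1.0, 1e9)
        np.testing.assert_allclose(d, [2, 4], atol=1e-6)

    @settings(derandomize=True, max_examples=50)
    @given(r=st.floats(-50, 50), n=st.integers(1, 10),
           nu=st.floats(2.1, 50), tau2=st.floats(0.01, 10))
    def test_bounded_by_replication_count(self, r, n, nu, tau2):
        d = tmap_weights(np.array([r]), np.array([float(n)]), tau2, nu)
        assert 0 < d[0] <= n + 1e-12


class TestTmap:
    def test_gaussian_limit_matches_gblup(self, clean_model, clean_sim):
        p = clean_sim.params_true
        fg = fit_gblup(clean_model, p)
        ft = fit_tmap(clean_model,
                      DispersionParams(p.sigma_g2, p.sigma_e2, nu=1e6))
        rel = np.max(np.abs(ft.g - fg.g)) / np.max(np.abs(fg.g))
        assert rel < 1e-4
        assert spearmanr(ft.g, fg.g).statistic > 0.999

    def test_scalar_posterior_mode(self):
        data = ModelData(y=np.array([2.0]), K=SCALAR_K)
        fit = fit_tmap(data, SCALAR_TMAP_PARAMS, tol=1e-12)
        assert fit.converged
        assert fit.g[0] == pytest.approx(SCALAR_TMAP_GHAT, abs=1e-6)

    def test_zero_data_zero_mode(self, small_K):
        fit = fit_tmap(ModelData(y=np.zeros(10), K=small_K),
                       DispersionParams(1.0, 1.0, nu=4.0))
        np.testing.assert_allclose(fit.g, 0, atol=1e-12)

    def test_objective_ascends(self, contaminated_sim):
        data = ModelData(y=contaminated_sim.y - contaminated_sim.y.mean(),
                         K=contaminated_sim.K)
        p = contaminated_sim.params_true
        fit = fit_tmap(data, DispersionParams(p.sigma_g2, p.sigma_e2, nu=4.0))
        diffs = np.diff(fit.objective_trace)
        assert np.all(diffs >= -1e-10)

    def test_fixed_point_residual_small(self, contaminated_sim):
        data = ModelData(y=contaminated_sim.y - contaminated_sim.y.mean(),
                         K=contaminated_sim.K)
        p = contaminated_sim.params_true
        params = DispersionParams(p.sigma_g2, p.sigma_e2, nu=4.0)
        tol = 1e-8
        fit = fit_tmap(data, params, tol=tol, max_iter=500)
        assert fit.converged
        d = fit.weights
        res = d * fit.g + params.lambda_dprime * (
            data.K.inverse() @ fit.g) - d * data.y
        assert np.max(np.abs(res)) < 10 * tol

    def test_weight_bounds_hold_at_solution(self, contaminated_sim):
        data = ModelData(y=contaminated_sim.y, K=contaminated_sim.K)
        p = contaminated_sim.params_true
        fit = fit_tmap(data, DispersionParams(p.sigma_g2, p.sigma_e2, nu=4.0))
        assert np.all(fit.weights > 0)
        assert np.all(fit.weights <= data.n_counts + 1e-12)

    def test_permutation_equivariance(self, clean_sim):
        y = clean_sim.y[:30]
        K = clean_sim.K.subset(np.arange(30))
        p = DispersionParams(0.3, 0.7, nu=4.0)
        fit = fit_tmap(ModelData(y=y, K=K), p)
        perm = np.random.default_rng(0).permutation(30)
        fit_p = fit_tmap(ModelData(y=y[perm], K=K.subset(perm)), p)
        np.testing.assert_allclose(fit_p.g, fit.g[perm], atol=1e-8)


class TestTmapNewton:
    def test_scalar_posterior_mode(self):
        data = ModelData(y=np.array([2.0]), K=SCALAR_K)
        fit = fit_tmap_newton(data, SCALAR_TMAP_PARAMS, tol=1e-10)
        assert fit.converged
        assert fit.g[0] == pytest.approx(SCALAR_TMAP_GHAT, abs=1e-6)

    def test_agrees_with_functional_iteration(self, clean_sim):
        y = clean_sim.y[:20] - np.mean(clean_sim.y[:20])
        K = clean_sim.K.subset(np.arange(20))
        params = DispersionParams(0.3, 0.7, nu=4.0)
        data = ModelData(y=y, K=K)
        f1 = fit_tmap(data, params, tol=1e-12, max_iter=2000)
        f2 = fit_tmap_newton(data, params, tol=1e-12)
        assert f1.converged and f2.converged
        np.testing.assert_allclose(f1.g, f2.g, atol=1e-6)

    def test_gaussian_limit(self, clean_model, clean_sim):
        p = clean_sim.params_true
        fg = fit_gblup(clean_model, p)
        fn = fit_tmap_newton(
            clean_model, DispersionParams(p.sigma_g2, p.sigma_e2, nu=1e6))
        rel = np.max(np.abs(fn.g - fg.g)) / np.max(np.abs(fg.g))
        assert rel < 1e-4

    def test_converges_in_fewer_iterations(self, contaminated_sim):
        data = ModelData(y=contaminated_sim.y - contaminated_sim.y.mean(),
                         K=contaminated_sim.K)
        p = contaminated_sim.params_true
        params = DispersionParams(p.sigma_g2, p.sigma_e2, nu=4.0)
        f1 = fit_tmap(data, params, tol=1e-10, max_iter=1000)
        f2 = fit_tmap_newton(data, params, tol=1e-10)
        assert f2.converged
        assert f2.n_iter <= f1.n_iter


class TestLmapWeights:
    def test_hand_value(self):
        m = lmap_weights(np.array([0.5]), np.array([1.0]), 1e-8)
        assert m[0] == pytest.approx(2.0)

    def test_zero_residual_capped_at_floor(self):
        m = lmap_weights(np.array([0.0]), np.array([3.0]), 1e-4)
        assert m[0] == pytest.approx(3.0 / 1e-4)

    @settings(derandomize=True, max_examples=50)
    @given(r=st.floats(0.01, 100), c=st.floats(0.1, 10))
    def test_scaling_homogeneity(self, r, c):
        m1 = lmap_weights(np.array([r]), np.array([1.0]), 1e-12)
        m2 = lmap_weights(np.array([c * r]), np.array([1.0]), 1e-12)
        assert m2[0] == pytest.approx(m1[0] / c, rel=1e-9)


class TestLmap:
    def test_scalar_l1_minimizer(self):
        # K=1, y=1, omega=2: J(g) = |1-g| + g^2, minimized at 0.5
        params = DispersionParams(sigma_g2=1.0, sigma_e2=4 * np.sqrt(2))
        assert params.omega == pytest.approx(2.0)
        fit = fit_lmap(ModelData(y=np.array([1.0]), K=SCALAR_K), params,
                       tol=1e-12, obj_tol=0.0)
        assert fit.g[0] == pytest.approx(0.5, abs=1e-9)

    def test_sign_equivariance(self, clean_sim):
        y = clean_sim.y[:25]
        K = clean_sim.K.subset(np.arange(25))
        params = DispersionParams(0.3, 0.7)
        f_pos = fit_lmap(ModelData(y=y, K=K), params)
        f_neg = fit_lmap(ModelData(y=-y, K=K), params)
        np.testing.assert_allclose(f_neg.g, -f_pos.g, atol=1e-6)

    def test_total_shrinkage_large_omega(self, clean_model):
        fit = fit_lmap(clean_model, DispersionParams(1e-4, 1e4))
        assert np.max(np.abs(fit.g)) < 1e-3

    def test_objective_descends(self, contaminated_sim):
        data = ModelData(y=contaminated_sim.y - contaminated_sim.y.mean(),
                         K=contaminated_sim.K)
        fit = fit_lmap(data, contaminated_sim.params_true)
        diffs = np.diff(fit.objective_trace)
        assert np.all(diffs <= 1e-10)

    def test_near_gaussian_ranking_tracks_gblup(self, clean_model, clean_sim):
        """LMAP on clean Gaussian data ranks individuals much like GBLUP,
        though not identically: the L1 loss and the weaker omega penalty
        reshuffle mid-ranked individuals even without outliers."""
        p = clean_sim.params_true
        fg = fit_gblup(clean_model, p)
        fl = fit_lmap(clean_model, p)
        assert spearmanr(fl.g, fg.g).statistic > 0.9

    def test_subgradient_optimality(self, clean_sim):
        """At the L1 optimum, omega (K^-1 g)_i equals n_i sign(r_i) for
        records the fit does not interpolate, and lies within [-n_i, n_i]
        for interpolated ones."""
        y = clean_sim.y[:40] - np.mean(clean_sim.y[:40])
        K = clean_sim.K.subset(np.arange(40))
        data = ModelData(y=y, K=K)
        params = clean_sim.params_true
        floor = 1e-8 * float(np.std(y))
        fit = fit_lmap(data, params, max_iter=5000)
        assert fit.converged
        r = y - fit.g
        v = params.omega * (K.inverse() @ fit.g)
        active = np.abs(r) > 1e3 * floor
        np.testing.assert_allclose(v[active], np.sign(r[active]), atol=1e-3)
        assert np.all(np.abs(v[~active]) <= 1.0 + 1e-6)


class TestPosteriorCovariance:
    def test_tmap_limit_is_gaussian_covariance(self):
        data = random_instance(5, n=10, with_W=False)
        params_g = DispersionParams(0.5, 1.0)
        params_t = DispersionParams(0.5, 1.0, nu=1e6)
        fg = fit_gblup(data, params_g)
        ft = fit_tmap(data, params_t)
        Vg = posterior_covariance(fg, data, params_g).matrix
        Vt = posterior_covariance(ft, data, params_t).matrix
        rel = np.max(np.abs(Vt - Vg)) / np.max(np.abs(Vg))
        assert rel < 1e-4

    def test_scalar_gaussian_variance(self):
        params = DispersionParams(1.0, 1.0)  # lambda = 1
        data = ModelData(y=np.array([0.7]), K=SCALAR_K)
        fit = fit_gblup(data, params)
        pc = posterior_covariance(fit, data, params)
        assert pc.matrix[0, 0] == pytest.approx(
            params.sigma_e2 / (1 + params.lam))
        assert pc.psd_flag

    def test_large_residual_flips_q_sign(self):
        # one huge residual makes q_i = d_i(1 - 2 d_i s_i) negative
        K = KinshipMatrix(list("ab"), np.eye(2) * 0.05)
        data = ModelData(y=np.array([0.1, 30.0]), K=K)
        params = DispersionParams(sigma_g2=0.05, sigma_e2=1.0, nu=4.0)
        fit = fit_tmap(data, params, tol=1e-12)
        r = data.y - fit.g
        s = r ** 2 / (params.tau_e2 * params.nu)
        q = fit.weights * (1 - 2 * fit.weights * s)
        assert q.min() < 0
        pc = posterior_covariance(fit, data, params)
        eigmin = np.min(np.linalg.eigvalsh(
            np.linalg.inv(pc.matrix)))  # sign of curvature
        assert pc.psd_flag == bool(eigmin >= -1e-10)

    def test_requires_converged_fit(self, clean_model, clean_sim):
        p = clean_sim.params_true
        fit = fit_gblup(clean_model, p)
        fit.converged = False
        with pytest.raises(ValueError, match="converged"):
            posterior_covariance(fit, clean_model, p)


class TestEffectiveShrinkage:
    def test_gblup_constant_lambda(self, clean_model, clean_sim):
        p = clean_sim.params_true
        es = effective_shrinkage(fit_gblup(clean_model, p), p)
        np.testing.assert_allclose(es, p.lam)

    def test_tmap_definitional(self, contaminated_sim):
        data = ModelData(y=contaminated_sim.y, K=contaminated_sim.K)
        p = contaminated_sim.params_true
        params = DispersionParams(p.sigma_g2, p.sigma_e2, nu=4.0)
        fit = fit_tmap(data, params)
        np.testing.assert_allclose(
            effective_shrinkage(fit, params),
            params.lambda_dprime / fit.weights)

    @pytest.mark.parametrize("method", ["tmap", "lmap"])
    def test_monotone_in_absolute_residual(self, contaminated_sim, method):
        data = ModelData(y=contaminated_sim.y - contaminated_sim.y.mean(),
                         K=contaminated_sim.K)
        p = contaminated_sim.params_true
        if method == "tmap":
            params = DispersionParams(p.sigma_g2, p.sigma_e2, nu=4.0)
            fit = fit_tmap(data, params)
        else:
            params = p
            fit = fit_lmap(data, params)
        es = effective_shrinkage(fit, params)
        resid = np.abs(data.y - fit.g)
        order = np.argsort(resid)
        assert np.all(np.diff(es[order]) >= -1e-10)
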