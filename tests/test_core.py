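"""Unit and property tests for the base GTM model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp

import gtmview as gv
from gtmview.core import (FitConfig, GTMModel, LatentGrid, basis_jacobian,
                          init_model, m_step)

from conftest import small_random_model


# ---------------------------------------------------------------------------
# lattice and basis


class TestMakeGrid:
    def test_reference_size(self):
        assert gv.make_grid((20, 20)).n_points == 400

    def test_single_point_is_midpoint(self):
        lat = gv.make_grid((1, 1))
        np.testing.assert_array_equal(lat.points, [[0.0], [0.0]])

    def test_two_by_two_hits_extent_corners(self):
        lat = gv.make_grid((2, 2))
        got = set(map(tuple, lat.points.T))
        assert got == {(-1, -1), (1, -1), (-1, 1), (1, 1)}

    def test_row_major_even_spacing(self):
        lat = gv.make_grid((3, 5), extent=((0, 4), (0, 2)))
        pts = lat.points.reshape(2, 3, 5)
        np.testing.assert_allclose(pts[0, 0], [0, 1, 2, 3, 4])
        np.testing.assert_allclose(pts[1, :, 0], [0, 1, 2])

    @pytest.mark.parametrize("shape", [(0, 3), (3, 0), (-1, 2)])
    def test_rejects_nonpositive_dims(self, shape):
        with pytest.raises(ValueError):
            gv.make_grid(shape)


class TestMakeBasis:
    def test_reference_center_count(self):
        lat = gv.make_grid((20, 20))
        assert gv.make_basis(lat, (4, 4)).n_centers == 16

    def test_kernel_is_one_at_own_center(self):
        lat = gv.make_grid((5, 5))
        basis = gv.make_basis(lat, (2, 2), sigma2=0.5)
        phi = gv.design_matrix(basis, basis.centers)
        np.testing.assert_allclose(np.diag(phi), 1.0)

    def test_kernel_closed_form_at_two_sigma_sq(self):
        lat = gv.make_grid((5, 5))
        basis = gv.make_basis(lat, (1, 1), sigma2=0.5)
        # point at squared distance 2*sigma^2 from the center
        r = basis.centers[:, 0] + np.array([1.0, 0.0])
        phi = gv.design_matrix(basis, r[:, None])
        np.testing.assert_allclose(phi[0, 0], np.exp(-1.0))

    def test_single_center_needs_explicit_width(self):
        lat = gv.make_grid((5, 5))
        with pytest.raises(ValueError, match="sigma2"):
            gv.make_basis(lat, (1, 1))

    def test_width_is_factor_times_spacing(self):
        lat = gv.make_grid((5, 5))
        basis = gv.make_basis(lat, (3, 3), width_factor=2.0)
        # centers on [-1,1] at spacing 1; sigma = 2 * 1
        assert basis.width == pytest.approx(4.0)


class TestDesignMatrix:
    def test_unit_at_center(self):
        lat = gv.make_grid((3, 3))
        basis = gv.make_basis(lat, (3, 3))
        phi = gv.design_matrix(basis, basis.centers)
        np.testing.assert_allclose(np.diag(phi), 1.0)

    def test_matches_scalar_loop(self):
        pts = np.array([[-1.0, 0.0, 1.0], [0.5, -0.5, 0.0]])
        centers = np.array([[-0.5, 0.5], [0.0, 0.0]])
        basis = gv.RadialBasisSet(centers=centers, width=1.0)
        phi = gv.design_matrix(basis, pts)
        for j in range(3):
            for k in range(2):
                expect = np.exp(-np.sum((pts[:, j] - centers[:, k]) ** 2) / 2.0)
                assert phi[j, k] == pytest.approx(expect, abs=1e-15)

    def test_wide_kernels_approach_one(self):
        lat = gv.make_grid((4, 4))
        basis = gv.make_basis(lat, (2, 2), sigma2=1e12)
        phi = gv.design_matrix(basis, lat)
        np.testing.assert_allclose(phi, 1.0, atol=1e-10)

    def test_bias_column_first(self):
        lat = gv.make_grid((3, 3))
        basis = gv.make_basis(lat, (2, 2), has_bias=True)
        phi = gv.design_matrix(basis, lat)
        assert phi.shape == (9, 5)
        np.testing.assert_array_equal(phi[:, 0], 1.0)


# ---------------------------------------------------------------------------
# initialisation


class TestInitModel:
    def test_planar_data_gives_planar_manifold(self):
        rng = np.random.default_rng(0)
        basis_vecs = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0],
                               [0.0, 0.0]]).T  # plane = span(e1,e2) in R^4
        coeffs = rng.standard_normal((2, 80))
        X = basis_vecs.T @ coeffs  # 4 x 80, lies in the e1-e2 plane
        lattice = gv.make_grid((5, 5))
        basis = gv.make_basis(lattice, (3, 3))
        model = init_model(X, lattice, basis)
        # manifold coordinates outside the plane are numerically zero
        assert np.abs(model.manifold[2:, :]).max() < 1e-8

    def test_deterministic(self, five_clusters):
        data, _ = five_clusters
        lattice = gv.make_grid((6, 6))
        basis = gv.make_basis(lattice, (3, 3))
        m1 = init_model(data, lattice, basis, FitConfig(seed=7))
        m2 = init_model(data, lattice, basis, FitConfig(seed=7))
        np.testing.assert_array_equal(m1.W, m2.W)
        assert m1.beta == m2.beta

    def test_finite_on_cluster_fixture(self, five_clusters):
        data, _ = five_clusters
        lattice = gv.make_grid((10, 10))
        basis = gv.make_basis(lattice, (4, 4))
        model = init_model(data, lattice, basis)
        assert np.all(np.isfinite(model.W))
        assert np.isfinite(model.beta) and model.beta > 0

    def test_zero_variance_data_rejected(self):
        X = np.ones((3, 10))
        lattice = gv.make_grid((3, 3))
        basis = gv.make_basis(lattice, (2, 2))
        with pytest.raises(ValueError):
            init_model(X, lattice, basis)


# ---------------------------------------------------------------------------
# E-step / M-step / likelihood


def scalar_loop_responsibilities(X, Y, beta):
    """Naive per-pair evaluation of the posterior responsibilities."""
    N, J = X.shape[1], Y.shape[1]
    p = X.shape[0]
    R = np.zeros((N, J))
    for i in range(N):
        dens = np.array([
            (beta / (2 * np.pi)) ** (p / 2)
            * np.exp(-beta / 2 * np.sum((X[:, i] - Y[:, j]) ** 2))
            for j in range(J)])
        R[i] = dens / dens.sum()
    return R


def scalar_loop_loglik(X, Y, beta):
    N, J = X.shape[1], Y.shape[1]
    p = X.shape[0]
    total = 0.0
    for i in range(N):
        mix = np.mean([
            (beta / (2 * np.pi)) ** (p / 2)
            * np.exp(-beta / 2 * np.sum((X[:, i] - Y[:, j]) ** 2))
            for j in range(J)])
        total += np.log(mix)
    return total


def _model_from_manifold(Y, beta, points=None):
    """Wrap an explicit manifold as a model (W solved through the basis)."""
    J = Y.shape[1]
    if points is None:
        points = np.vstack([np.linspace(-1, 1, J) if J > 1 else [0.0],
                            np.zeros(J)])
    lattice = LatentGrid(points=points, grid_shape=(1, J))
    basis = gv.RadialBasisSet(centers=points.copy(), width=1.0)
    phi = gv.design_matrix(basis, lattice)
    W = np.linalg.solve(phi.T @ phi + 1e-12 * np.eye(J), phi.T @ Y.T).T
    return GTMModel(lattice=lattice, basis=basis, W=W, beta=beta, manifold=Y)


class TestEStep:
    def test_single_component_takes_all(self):
        X = np.random.default_rng(0).standard_normal((2, 5))
        model = _model_from_manifold(np.zeros((2, 1)), beta=1.0)
        R = gv.e_step(model, X)
        np.testing.assert_array_equal(R, np.ones((5, 1)))

    def test_equidistant_point_splits_evenly(self):
        Y = np.array([[-1.0, 1.0], [0.0, 0.0]])
        model = _model_from_manifold(Y, beta=2.0)
        R = gv.e_step(model, np.array([[0.0], [5.0]]))
        np.testing.assert_allclose(R, [[0.5, 0.5]])

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((3, 3))
        Y = rng.standard_normal((3, 4))
        model = _model_from_manifold(Y, beta=1.7)
        R = gv.e_step(model, X)
        np.testing.assert_allclose(R, scalar_loop_responsibilities(X, Y, 1.7),
                                   atol=1e-12)

    @given(beta=st.floats(min_value=1e-6, max_value=1e6),
           seed=st.integers(0, 100))
    @settings(max_examples=40, deadline=None)
    def test_rows_sum_to_one_even_at_extreme_beta(self, beta, seed):
        rng = np.random.default_rng(seed)
        model = small_random_model(rng)
        model = GTMModel(lattice=model.lattice, basis=model.basis, W=model.W,
                         beta=beta, manifold=model.manifold)
        X = rng.standard_normal((3, 6)) * 10
        R = gv.e_step(model, X)
        assert np.all(R >= 0)
        np.testing.assert_allclose(R.sum(axis=1), 1.0, atol=1e-10)


class TestMStep:
    def test_single_component_lands_on_data_mean(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((2, 7))
        model = _model_from_manifold(np.zeros((2, 1)), beta=1.0)
        R = np.ones((7, 1))
        out = m_step(model, X, R, FitConfig(ridge=0.0))
        np.testing.assert_allclose(out.manifold[:, 0], X.mean(axis=1),
                                   atol=1e-10)

    def test_beta_equals_weighted_mean_squared_residual(self):
        rng = np.random.default_rng(2)
        model = small_random_model(rng)
        X = rng.standard_normal((3, 8))
        R = gv.e_step(model, X)
        out = m_step(model, X, R)
        p, N = X.shape
        resid = 0.0
        for i in range(N):
            for j in range(out.manifold.shape[1]):
                resid += R[i, j] * np.sum((X[:, i] - out.manifold[:, j]) ** 2)
        np.testing.assert_allclose(1.0 / out.beta, resid / (N * p), rtol=1e-10)

    def test_ridge_continuity(self):
        rng = np.random.default_rng(4)
        model = small_random_model(rng)
        X = rng.standard_normal((3, 30))
        R = gv.e_step(model, X)
        w0 = m_step(model, X, R, FitConfig(ridge=0.0)).W
        w1 = m_step(model, X, R, FitConfig(ridge=1e-12)).W
        assert np.abs(w0 - w1).max() < 1e-6


class TestLogLikelihood:
    def test_unit_density_point(self):
        # p=1, beta=2*pi: density at zero residual is exactly 1
        points = np.array([[0.0], [0.0]])
        lattice = LatentGrid(points=points, grid_shape=(1, 1))
        basis = gv.RadialBasisSet(centers=points, width=1.0)
        model = GTMModel(lattice=lattice, basis=basis,
                         W=np.zeros((1, 1)), beta=2 * np.pi,
                         manifold=np.zeros((1, 1)))
        assert gv.log_likelihood(model, np.zeros((1, 4))) == pytest.approx(0.0)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((2, 3))
        Y = rng.standard_normal((2, 4))
        model = _model_from_manifold(Y, beta=0.9)
        np.testing.assert_allclose(gv.log_likelihood(model, X),
                                   scalar_loop_loglik(X, Y, 0.9), atol=1e-12)

    def test_duplicate_lattice_point_is_neutral(self):
        # duplicating a component whose density equals the mixture mean
        # leaves log( (1/J) sum_j p_j ) unchanged; duplicating the sole
        # component of a J=1 model is the exact instance of that algebra
        rng = np.random.default_rng(6)
        X = rng.standard_normal((2, 5))
        Y = rng.standard_normal((2, 1))
        m1 = _model_from_manifold(Y, beta=1.1)
        m2 = _model_from_manifold(np.hstack([Y, Y]), beta=1.1,
                                  points=np.zeros((2, 2)))
        np.testing.assert_allclose(gv.log_likelihood(m2, X),
                                   gv.log_likelihood(m1, X), atol=1e-12)


class TestFit:
    def test_loglik_monotone_and_deterministic(self, fitted_model):
        _, trace, _, _ = fitted_model
        ll = trace.log_likelihoods
        assert np.all(np.diff(ll) >= -1e-8 * np.abs(ll[:-1]))

    def test_two_runs_identical(self, five_clusters):
        data, _ = five_clusters
        lattice = gv.make_grid((6, 6))
        basis = gv.make_basis(lattice, (3, 3))
        cfg = FitConfig(max_iter=20)
        m1, t1 = gv.fit(data, lattice, basis, cfg)
        m2, t2 = gv.fit(data, lattice, basis, cfg)
        np.testing.assert_array_equal(m1.W, m2.W)
        np.testing.assert_array_equal(t1.log_likelihoods, t2.log_likelihoods)

    def test_monotone_on_random_small_problems(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            X = rng.standard_normal((3, 20)) * rng.uniform(0.5, 2)
            lattice = gv.make_grid((3, 3))
            basis = gv.make_basis(lattice, (2, 2))
            _, trace = gv.fit(X, lattice, basis, FitConfig(max_iter=25))
            ll = trace.log_likelihoods
            assert np.all(np.diff(ll) >= -1e-8 * np.abs(ll[:-1]))

    def test_topographic_recovery(self, fitted_model, five_clusters):
        from sklearn.cluster import KMeans
        from sklearn.metrics import adjusted_rand_score
        model, _, data, labels = fitted_model
        coords = gv.project(model, data)
        pred = KMeans(5, n_init=10, random_state=0).fit_predict(coords)
        assert adjusted_rand_score(labels, pred) >= 0.8


class TestProject:
    def test_indicator_row_returns_lattice_point(self):
        rng = np.random.default_rng(7)
        model = small_random_model(rng)
        J = model.lattice.n_points
        R = np.zeros((1, J))
        R[0, 4] = 1.0
        for mode in ("mean", "mode"):
            got = gv.project(model, np.zeros((3, 1)), mode, resp=R)
            np.testing.assert_allclose(got[0], model.lattice.points[:, 4])

    def test_uniform_responsibility_centers_on_origin(self):
        rng = np.random.default_rng(8)
        model = small_random_model(rng, grid=(5, 5))
        J = model.lattice.n_points
        R = np.full((1, J), 1.0 / J)
        got = gv.project(model, np.zeros((3, 1)), "mean", resp=R)
        np.testing.assert_allclose(got[0], [0.0, 0.0], atol=1e-12)

    def test_one_dimensional_mean(self):
        points = np.array([[-1.0, 1.0], [0.0, 0.0]])
        lattice = LatentGrid(points=points, grid_shape=(1, 2))
        basis = gv.RadialBasisSet(centers=points, width=1.0)
        model = GTMModel(lattice=lattice, basis=basis, W=np.zeros((2, 2)),
                         beta=1.0, manifold=np.zeros((2, 2)))
        got = gv.project(model, np.zeros((2, 1)), "mean",
                         resp=np.array([[0.25, 0.75]]))
        assert got[0, 0] == pytest.approx(0.5)

    def test_mean_projection_inside_lattice_bbox(self, fitted_model):
        model, _, data, _ = fitted_model
        coords = gv.project(model, data)
        lo = model.lattice.points.min(axis=1)
        hi = model.lattice.points.max(axis=1)
        assert np.all(coords >= lo - 1e-12) and np.all(coords <= hi + 1e-12)


class TestRotationEquivariance:
    def test_responsibilities_unchanged_by_rigid_rotation(self, five_clusters):
        data, _ = five_clusters
        lattice = gv.make_grid((5, 5))
        basis = gv.make_basis(lattice, (3, 3))
        model = init_model(data, lattice, basis)
        theta = 0.7
        Q = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0],
                      [0, 0, 1.0]])
        R1 = gv.e_step(model, data)
        rotated = GTMModel(lattice=lattice, basis=basis, W=Q @ model.W,
                           beta=model.beta, manifold=Q @ model.manifold)
        R2 = gv.e_step(rotated, Q @ data.values)
        np.testing.assert_allclose(R1, R2, atol=1e-10)


# ---------------------------------------------------------------------------
# magnification


def identity_embedding(scale=1.0):
    """A model whose analytic Jacobian at the (single) lattice point r=0 is
    exactly scale * I: antisymmetric kernel pairs along each latent axis."""
    a, s2 = 0.6, 0.5
    centers = np.array([[a, -a, 0.0, 0.0], [0.0, 0.0, a, -a]])
    basis = gv.RadialBasisSet(centers=centers, width=s2)
    c = scale * s2 / (2 * a * np.exp(-a * a / (2 * s2)))
    W = np.array([[c, -c, 0.0, 0.0], [0.0, 0.0, c, -c]])
    points = np.zeros((2, 1))
    lattice = LatentGrid(points=points, grid_shape=(1, 1))
    phi = gv.design_matrix(basis, lattice)
    return GTMModel(lattice=lattice, basis=basis, W=W, beta=1.0,
                    manifold=W @ phi.T)


def fd_magnification(model, eps=1e-6):
    """Central-finite-difference oracle for the areal factor."""
    out = np.empty(model.lattice.n_points)
    for j in range(model.lattice.n_points):
        r = model.lattice.points[:, j]
        cols = []
        for d in range(2):
            hi = r.copy(); hi[d] += eps
            lo = r.copy(); lo[d] -= eps
            y = gv.manifold_at(model, np.column_stack([hi, lo]))
            cols.append((y[:, 0] - y[:, 1]) / (2 * eps))
        jac = np.column_stack(cols)
        out[j] = np.sqrt(max(np.linalg.det(jac.T @ jac), 0.0))
    return out


class TestMagnification:
    def test_identity_jacobian_gives_factor_one(self):
        model = identity_embedding(1.0)
        np.testing.assert_allclose(gv.magnification(model), [1.0], rtol=1e-12)

    def test_isotropic_stretch_gives_factor_s_squared(self):
        model = identity_embedding(3.0)
        np.testing.assert_allclose(gv.magnification(model), [9.0], rtol=1e-12)

    def test_matches_finite_difference_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            p = int(rng.integers(2, 6))
            model = small_random_model(rng, p=p, grid=(3, 3),
                                       basis_shape=(2, 2))
            got = gv.magnification(model)
            expect = fd_magnification(model)
            np.testing.assert_allclose(got, expect, atol=1e-4)
            assert np.all(got >= 0)

    def test_zero_loadings_flagged(self):
        rng = np.random.default_rng(13)
        model = small_random_model(rng)
        flat = GTMModel(lattice=model.lattice, basis=model.basis,
                        W=np.zeros_like(model.W), beta=1.0,
                        manifold=np.zeros_like(model.manifold))
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            factors = gv.magnification(flat)
        np.testing.assert_array_equal(factors, 0.0)
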