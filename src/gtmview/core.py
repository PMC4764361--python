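"""Core Generative Topographic Mapping model.

GTM models high-dimensional data ``x`` (p x N) as an equal-weight constrained
Gaussian mixture whose component means lie on a smooth image of a regular 2-D
latent lattice: ``y_j = W Phi(r_j)`` where ``Phi`` is a bank of radially
symmetric Gaussian basis functions ("attractors") over the latent space and
``W`` is a p x K loading matrix.  Each observation is modelled as an isotropic
Gaussian around one of the ``y_j`` with shared precision ``beta``.  Fitting
alternates posterior-responsibility E-steps with closed-form M-steps (EM).

Observations are plotted at the posterior mean of the latent variable,
``sum_j R_ij r_j``; local stretch of the latent-to-data map is summarised by
an areal magnification factor ``sqrt(det(J^T J))`` of the map's Jacobian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

__all__ = [
    "LatentGrid",
    "RadialBasisSet",
    "DataMatrix",
    "GTMModel",
    "AnchorComponent",
    "BlendLayer",
    "FitConfig",
    "FitTrace",
    "make_grid",
    "append_grid_point",
    "make_basis",
    "append_basis_center",
    "design_matrix",
    "basis_jacobian",
    "manifold_at",
    "init_model",
    "e_step",
    "m_step",
    "fit",
    "log_likelihood",
    "project",
    "magnification",
    "as_values",
]

DEFAULT_EXTENT = ((-1.0, 1.0), (-1.0, 1.0))


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class LatentGrid:
    """Regular rectangular lattice of latent points, plus any appended anchors.

    ``points`` is q x J; the first ``rows*cols`` columns form the regular
    base grid (row-major), any further columns are user-added anchor points.
    """

    points: np.ndarray
    grid_shape: tuple[int, int]
    extent: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_EXTENT

    @property
    def n_points(self) -> int:
        return self.points.shape[1]

    @property
    def n_dim(self) -> int:
        return self.points.shape[0]

    @property
    def n_base(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def diameter(self) -> float:
        lo = self.points.min(axis=1)
        hi = self.points.max(axis=1)
        return float(np.linalg.norm(hi - lo))


@dataclass(frozen=True)
class RadialBasisSet:
    """Gaussian basis functions: centers (q x K) and shared width sigma^2.

    ``has_bias`` prepends a constant column to the design matrix (off by
    default; the plain kernel bank is the standard parameterisation here).
    """

    centers: np.ndarray
    width: float  # sigma^2, in squared latent units
    has_bias: bool = False

    @property
    def n_centers(self) -> int:
        return self.centers.shape[1]

    @property
    def n_columns(self) -> int:
        return self.n_centers + int(self.has_bias)


@dataclass(frozen=True)
class DataMatrix:
    """Observed data, stored p x N (variables in rows)."""

    values: np.ndarray
    ids: tuple[str, ...] | None = None
    var_names: tuple[str, ...] | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("data must be a 2-D matrix (p x N)")
        if not np.all(np.isfinite(v)):
            raise ValueError("data contains non-finite entries")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_rows(cls, rows: np.ndarray, ids=None, var_names=None) -> "DataMatrix":
        """Build from the on-disk orientation (one observation per row)."""
        return cls(np.asarray(rows, dtype=float).T,
                   tuple(ids) if ids is not None else None,
                   tuple(var_names) if var_names is not None else None)

    @property
    def n_obs(self) -> int:
        return self.values.shape[1]

    @property
    def n_vars(self) -> int:
        return self.values.shape[0]


def as_values(data) -> np.ndarray:
    """Return the p x N value matrix of a DataMatrix or array-like."""
    if isinstance(data, DataMatrix):
        return data.values
    return np.asarray(data, dtype=float)


@dataclass(frozen=True)
class AnchorComponent:
    """A user-added mixture component: pinned observation + scaled density.

    ``weights`` holds the per-observation residual multipliers V(Delta_i) for
    this component's likelihood; None means V == 1 (unscaled).
    """

    obs_index: int
    lattice_index: int
    basis_index: int
    weights: np.ndarray | None = None


@dataclass(frozen=True)
class BlendLayer:
    """One step of the manifold-mixture recursion.

    The base layer has ``r_star is None`` and evaluates ``W Phi(r)``
    directly; each later layer blends the accumulated manifold with its own
    ``W Phi`` using delta(r) = min(||r - r*|| / b, 1).
    """

    W: np.ndarray
    basis: RadialBasisSet
    r_star: np.ndarray | None = None
    b: float | None = None


@dataclass(frozen=True)
class GTMModel:
    lattice: LatentGrid
    basis: RadialBasisSet
    W: np.ndarray  # p x n_columns
    beta: float
    manifold: np.ndarray  # p x J, cached (may be a stage-3 blend)
    anchors: tuple[AnchorComponent, ...] = ()
    blend_layers: tuple[BlendLayer, ...] = ()

    @property
    def n_vars(self) -> int:
        return self.W.shape[0]

    @property
    def is_blended(self) -> bool:
        return len(self.blend_layers) > 0


@dataclass(frozen=True)
class FitConfig:
    max_iter: int = 200
    rel_tol: float = 1e-5
    ridge: float = 1e-6
    seed: int = 0
    init: str = "pca"

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be > 0")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")


@dataclass(frozen=True)
class FitTrace:
    log_likelihoods: np.ndarray
    converged: bool
    n_iter: int


# ---------------------------------------------------------------------------
# lattice and basis construction


def make_grid(grid_shape: tuple[int, int],
              extent=DEFAULT_EXTENT) -> LatentGrid:
    """Regular rows x cols lattice spanning ``extent``, row-major order.

    A single point along an axis sits at the axis midpoint.
    """
    rows, cols = int(grid_shape[0]), int(grid_shape[1])
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be positive")
    (x0, x1), (y0, y1) = extent
    xs = np.linspace(x0, x1, cols) if cols > 1 else np.array([(x0 + x1) / 2.0])
    ys = np.linspace(y0, y1, rows) if rows > 1 else np.array([(y0 + y1) / 2.0])
    # row-major: row index varies slowest
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    pts = np.vstack([gx.ravel(), gy.ravel()])
    return LatentGrid(points=pts, grid_shape=(rows, cols),
                      extent=((float(x0), float(x1)), (float(y0), float(y1))))


def append_grid_point(lattice: LatentGrid, r: np.ndarray) -> LatentGrid:
    """Return a lattice with one extra (anchor) point appended."""
    r = np.asarray(r, dtype=float).reshape(-1)
    if r.shape[0] != lattice.n_dim:
        raise ValueError("anchor point dimension mismatch")
    if not np.all(np.isfinite(r)):
        raise ValueError("anchor point must be finite")
    pts = np.hstack([lattice.points, r[:, None]])
    return replace(lattice, points=pts)


def make_basis(lattice: LatentGrid,
               basis_shape: tuple[int, int],
               width_factor: float = 1.0,
               sigma2: float | None = None,
               has_bias: bool = False) -> RadialBasisSet:
    """K Gaussian centers on a regular sub-grid of the lattice extent.

    sigma = width_factor x spacing between adjacent centers (the width that
    makes neighbouring kernels overlap and cover the latent space).  With a
    single center there is no spacing, so ``sigma2`` must be given.
    """
    rows, cols = int(basis_shape[0]), int(basis_shape[1])
    if rows < 1 or cols < 1:
        raise ValueError("basis dimensions must be positive")
    if width_factor <= 0:
        raise ValueError("width_factor must be > 0")
    sub = make_grid((rows, cols), lattice.extent)
    centers = sub.points
    if sigma2 is None:
        spacings = []
        (x0, x1), (y0, y1) = lattice.extent
        if cols > 1:
            spacings.append((x1 - x0) / (cols - 1))
        if rows > 1:
            spacings.append((y1 - y0) / (rows - 1))
        if not spacings:
            raise ValueError(
                "a 1x1 basis has no center spacing; supply sigma2 explicitly")
        sigma = width_factor * float(np.mean(spacings))
        sigma2 = sigma * sigma
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    return RadialBasisSet(centers=centers, width=float(sigma2), has_bias=has_bias)


def append_basis_center(basis: RadialBasisSet, mu: np.ndarray) -> RadialBasisSet:
    mu = np.asarray(mu, dtype=float).reshape(-1)
    return replace(basis, centers=np.hstack([basis.centers, mu[:, None]]))


def design_matrix(basis: RadialBasisSet, points) -> np.ndarray:
    """Evaluate all basis columns at latent points: M x n_columns.

    Entry (j, k) = exp(-||r_j - mu_k||^2 / (2 sigma^2)).  The optional bias
    column of ones comes FIRST so that appended kernels keep stable trailing
    indices.
    """
    pts = points.points if isinstance(points, LatentGrid) else np.asarray(points, dtype=float)
    sq = cdist(pts.T, basis.centers.T, "sqeuclidean")
    phi = np.exp(-sq / (2.0 * basis.width))
    if basis.has_bias:
        phi = np.hstack([np.ones((phi.shape[0], 1)), phi])
    return phi


def basis_jacobian(basis: RadialBasisSet, r: np.ndarray) -> np.ndarray:
    """d Phi / d r at a single latent point: n_columns x q.

    For a Gaussian kernel, dPhi_k/dr = -((r - mu_k)/sigma^2) Phi_k(r); the
    bias column has zero derivative.
    """
    r = np.asarray(r, dtype=float).reshape(-1)
    diff = r[:, None] - basis.centers  # q x K
    phi = np.exp(-np.sum(diff ** 2, axis=0) / (2.0 * basis.width))  # K
    dphi = -(diff * phi[None, :]) / basis.width  # q x K
    out = dphi.T  # K x q
    if basis.has_bias:
        out = np.vstack([np.zeros((1, r.shape[0])), out])
    return out


def manifold_at(model: GTMModel, points) -> np.ndarray:
    """Evaluate the model's manifold at arbitrary latent points (p x M).

    Plain models evaluate ``W Phi(r)``.  After stage-3 interactions the
    manifold is a recursive mixture: each layer blends the accumulated
    surface with its own ``W Phi`` using delta(r) = min(||r - r*|| / b, 1),
    so the evaluation composes exactly across sequential moves.
    """
    pts = points.points if isinstance(points, LatentGrid) else np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if not model.blend_layers:
        return model.W @ design_matrix(model.basis, pts).T
    layers = model.blend_layers
    y = layers[0].W @ design_matrix(layers[0].basis, pts).T
    for layer in layers[1:]:
        y_u = layer.W @ design_matrix(layer.basis, pts).T
        d = np.linalg.norm(pts - layer.r_star[:, None], axis=0) / layer.b
        delta = np.clip(d, 0.0, 1.0)
        y = delta[None, :] * y + (1.0 - delta)[None, :] * y_u
    return y


# ---------------------------------------------------------------------------
# EM machinery


def _check_dims(model: GTMModel, X: np.ndarray) -> None:
    if X.shape[0] != model.n_vars:
        raise ValueError(
            f"data has {X.shape[0]} variables but model expects {model.n_vars}")


def _log_kernels(model: GTMModel, X: np.ndarray) -> np.ndarray:
    """N x J matrix of log unnormalised component kernels.

    Ordinary components use -beta/2 ||x_i - y_j||^2; anchor components scale
    the squared residual by their per-observation weights V(Delta_i).  The
    shared (beta/2pi)^{p/2} prefactor is omitted (it cancels in
    responsibilities and is restored in log_likelihood).
    """
    D = cdist(X.T, model.manifold.T, "sqeuclidean")
    L = -0.5 * model.beta * D
    for a in model.anchors:
        if a.weights is not None:
            L[:, a.lattice_index] = -0.5 * model.beta * a.weights * D[:, a.lattice_index]
    return L


def e_step(model: GTMModel, data) -> np.ndarray:
    """Posterior responsibilities R (N x J); rows sum to one.

    Anchored observations keep their pinned indicator rows; anchor
    components use their locally scaled likelihood for every observation.
    """
    X = as_values(data)
    _check_dims(model, X)
    L = _log_kernels(model, X)
    L -= L.max(axis=1, keepdims=True)
    R = np.exp(L)
    R /= R.sum(axis=1, keepdims=True)
    for a in model.anchors:
        R[a.obs_index, :] = 0.0
        R[a.obs_index, a.lattice_index] = 1.0
    return R


def m_step(model: GTMModel, data, resp: np.ndarray,
           config: FitConfig | None = None) -> GTMModel:
    """Closed-form update of W and beta given responsibilities.

    Solves the (ridge-regularised) weighted normal equations
    ``(Phi^T G Phi + ridge I) W^T = Phi^T R~ X^T`` with
    ``G = diag(colsums R~)``, where R~ folds anchor scaling weights into the
    responsibilities, then ``beta^{-1} = sum R~_ij ||x_i - y_j||^2 / (N p)``.
    """
    config = config or FitConfig()
    X = as_values(data)
    _check_dims(model, X)
    N = X.shape[1]
    p = X.shape[0]
    Rw = resp
    if any(a.weights is not None for a in model.anchors):
        Rw = resp.copy()
        for a in model.anchors:
            if a.weights is not None:
                Rw[:, a.lattice_index] = resp[:, a.lattice_index] * a.weights
    phi = design_matrix(model.basis, model.lattice)  # J x K
    G = Rw.sum(axis=0)
    A = phi.T @ (G[:, None] * phi)
    if config.ridge > 0:
        A = A + config.ridge * np.eye(A.shape[0])
    B = phi.T @ (Rw.T @ X.T)  # K x p
    try:
        Wt = np.linalg.solve(A, B)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular M-step normal equations; raise FitConfig.ridge") from err
    W = Wt.T
    manifold = W @ phi.T
    D = cdist(X.T, manifold.T, "sqeuclidean")
    beta_inv = float((Rw * D).sum()) / (N * p)
    beta = 1.0 / max(beta_inv, 1e-300)
    return replace(model, W=W, manifold=manifold, beta=beta, blend_layers=())


def log_likelihood(model: GTMModel, data) -> float:
    """Log-likelihood of the equal-weight mixture over lattice points.

    ``sum_i log( (1/J) sum_j p(x_i | y_j, beta) )`` computed in log space.
    Pinned (anchored) observations contribute only their own component's
    density, which makes this the objective conditional EM ascends.
    """
    X = as_values(data)
    _check_dims(model, X)
    p, N = X.shape
    J = model.lattice.n_points
    L = _log_kernels(model, X)
    per_obs = logsumexp(L, axis=1)
    for a in model.anchors:
        per_obs[a.obs_index] = L[a.obs_index, a.lattice_index]
    const = 0.5 * p * (np.log(model.beta) - np.log(2.0 * np.pi)) - np.log(J)
    return float(np.sum(per_obs + const))


def _pca(X: np.ndarray):
    """Eigen-decomposition of the data covariance, deterministic signs."""
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    cov = (Xc @ Xc.T) / max(X.shape[1] - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    # fix sign: largest-magnitude loading positive
    for k in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, k]))
        if vecs[i, k] < 0:
            vecs[:, k] = -vecs[:, k]
    return mean, np.clip(vals, 0.0, None), vecs


def init_model(data, lattice: LatentGrid, basis: RadialBasisSet,
               config: FitConfig | None = None) -> GTMModel:
    """PCA initialisation: the manifold starts on the top-q principal plane.

    Lattice points are mapped through the leading principal axes (scaled so
    the lattice spread matches the data spread along each axis) and W is the
    ridge least-squares fit of those targets.  beta^{-1} starts at the larger
    of the (q+1)-th PCA eigenvalue and half the squared spacing between
    adjacent manifold points.
    """
    config = config or FitConfig()
    X = as_values(data)
    p, N = X.shape
    q = lattice.n_dim
    if p < q:
        raise ValueError("data dimension must be >= latent dimension")
    if N < 2:
        raise ValueError("need at least 2 observations")
    mean, vals, vecs = _pca(X)
    if vals[0] <= 0:
        raise ValueError("zero-variance data cannot be initialised")
    pts = lattice.points  # q x J
    lat_sd = pts.std(axis=1)
    lat_sd[lat_sd == 0] = 1.0
    scale = np.sqrt(vals[:q]) / lat_sd
    targets = (mean[:, None] + (vecs[:, :q] * scale[None, :]) @ pts).T  # J x p
    phi = design_matrix(basis, lattice)
    A = phi.T @ phi + max(config.ridge, 1e-12) * np.eye(phi.shape[1])
    Wt = np.linalg.solve(A, phi.T @ targets)
    W = Wt.T
    manifold = W @ phi.T
    # adjacent-in-row manifold spacing
    rows, cols = lattice.grid_shape
    if cols > 1:
        base = manifold[:, :rows * cols]
        cube = base.reshape(p, rows, cols)
        sq_sp = float(np.mean(np.sum(np.diff(cube, axis=2) ** 2, axis=0)))
    elif rows > 1:
        base = manifold[:, :rows * cols]
        cube = base.reshape(p, rows, cols)
        sq_sp = float(np.mean(np.sum(np.diff(cube, axis=1) ** 2, axis=0)))
    else:
        sq_sp = 0.0
    lam_next = float(vals[q]) if p > q else 0.0
    beta_inv = max(lam_next, 0.5 * sq_sp)
    if beta_inv <= 0:
        beta_inv = float(vals[0])
    return GTMModel(lattice=lattice, basis=basis, W=W, beta=1.0 / beta_inv,
                    manifold=manifold)


def fit(data, lattice: LatentGrid, basis: RadialBasisSet,
        config: FitConfig | None = None) -> tuple[GTMModel, FitTrace]:
    """Fit GTM by EM from the PCA initialisation.

    Stops when the relative log-likelihood change drops below
    ``config.rel_tol`` or after ``config.max_iter`` iterations; non-
    convergence is reported on the trace, not raised.
    """
    config = config or FitConfig()
    model = init_model(data, lattice, basis, config)
    lls: list[float] = []
    converged = False
    prev = -np.inf
    for _ in range(config.max_iter):
        R = e_step(model, data)
        model = m_step(model, data, R, config)
        ll = log_likelihood(model, data)
        lls.append(ll)
        if np.isfinite(prev) and abs(ll - prev) <= config.rel_tol * abs(prev):
            converged = True
            break
        prev = ll
    return model, FitTrace(log_likelihoods=np.array(lls), converged=converged,
                           n_iter=len(lls))


# ---------------------------------------------------------------------------
# summaries


def project(model: GTMModel, data, mode: str = "mean",
            resp: np.ndarray | None = None) -> np.ndarray:
    """Latent coordinates for each observation (N x q).

    mode="mean" plots the posterior expectation sum_j R_ij r_j; mode="mode"
    the lattice point of maximal responsibility (ties -> lowest index).
    """
    if mode not in ("mean", "mode"):
        raise ValueError("mode must be 'mean' or 'mode'")
    R = e_step(model, data) if resp is None else resp
    if mode == "mean":
        return R @ model.lattice.points.T
    idx = np.argmax(R, axis=1)
    return model.lattice.points[:, idx].T


def magnification(model: GTMModel, eps: float = 1e-5) -> np.ndarray:
    """Areal magnification factor sqrt(det(J^T J)) at every lattice point.

    Plain models use the analytic Jacobian J = W dPhi/dr; blended manifolds
    fall back to central finite differences of the blend evaluation.  A
    rank-deficient Jacobian yields factor 0 with a warning.
    """
    pts = model.lattice.points
    q = pts.shape[0]
    factors = np.empty(pts.shape[1])
    for j in range(pts.shape[1]):
        r = pts[:, j]
        if model.is_blended:
            cols = []
            for d in range(q):
                hi = r.copy(); hi[d] += eps
                lo = r.copy(); lo[d] -= eps
                y = manifold_at(model, np.column_stack([hi, lo]))
                cols.append((y[:, 0] - y[:, 1]) / (2 * eps))
            jac = np.column_stack(cols)
        else:
            jac = model.W @ basis_jacobian(model.basis, r)
        g = jac.T @ jac
        det = float(np.linalg.det(g))
        factors[j] = np.sqrt(det) if det > 0 else 0.0
    if np.any(factors == 0):
        warnings.warn("rank-deficient Jacobian: zero magnification at some "
                      "lattice points", RuntimeWarning, stacklevel=2)
    return factors
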