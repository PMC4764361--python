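"""Visual-to-parametric interaction (V2PI) on a fitted GTM.

Moving a plotted observation to new latent coordinates re-parameterises the
model in up to three stages:

1. *Anchoring* — the lattice gains the chosen latent point r*, the basis
   gains an attractor kernel centred at mu* = r*, and the moved observation's
   responsibility row is pinned to the new component; the remaining
   parameters are re-estimated conditionally (EM with the pinned row).
2. *Scaling* — the anchor component's Gaussian is locally re-scaled in the
   spirit of local regression: its squared residual is multiplied by
   V(Delta_i) with Delta_i = ||x* - x_i|| / h, so observations near the moved
   point in data space gain responsibility at r* and follow it in the view.
3. *Manifold mixing* — the refit manifold is blended with the pre-move one,
   y_j <- delta_j y_j(current) + (1 - delta_j) y_j(user),
   delta_j = ||r_j - r*|| / b, b = max_j ||r_j - r*||, which confines the
   visual change to the neighbourhood of the anchor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import core
from .core import (AnchorComponent, BlendLayer, FitConfig, GTMModel,
                   append_basis_center, append_grid_point, as_values,
                   design_matrix, manifold_at)

__all__ = [
    "Anchor",
    "ScalingConfig",
    "InteractionRecord",
    "SCALING_FAMILIES",
    "bandwidth_from_neighbors",
    "scaling_weights",
    "add_anchor",
    "scaled_e_step",
    "conditional_refit",
    "mixing_weights",
    "blend_manifolds",
    "move_point",
    "replay",
]


def _v_delta(d):
    return d


def _v_delta2(d):
    return d ** 2


def _v_delta3(d):
    return d ** 3


def _v_exp_inv(d):
    out = np.zeros_like(d)
    nz = d > 0
    out[nz] = np.exp(-1.0 / d[nz])
    return out


def _v_exp_inv2(d):
    out = np.zeros_like(d)
    nz = d > 0
    out[nz] = np.exp(-1.0 / d[nz] ** 2)
    return out


def _v_none(d):
    return np.ones_like(d)


#: the scaling families found effective in practice; exp families are 0 at
#: Delta = 0 by continuity so the moved observation is maximally attracted.
SCALING_FAMILIES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "delta": _v_delta,
    "delta2": _v_delta2,
    "delta3": _v_delta3,
    "exp_inv": _v_exp_inv,
    "exp_inv2": _v_exp_inv2,
    "none": _v_none,
}


@dataclass(frozen=True)
class ScalingConfig:
    """Choice of scaling function V and bandwidth.

    Exactly one of ``bandwidth_h`` / ``neighbor_count`` must be set (unless
    family is "none", where the bandwidth is irrelevant).  A neighbour count
    m resolves to the distance from x* to its m-th nearest other observation,
    so that at least m points fall inside one bandwidth of the moved point.
    """

    family: str = "delta3"
    bandwidth_h: float | None = None
    neighbor_count: int | None = None

    def __post_init__(self):
        if self.family not in SCALING_FAMILIES:
            raise ValueError(f"unknown scaling family {self.family!r}; "
                             f"choose from {sorted(SCALING_FAMILIES)}")
        n_set = (self.bandwidth_h is not None) + (self.neighbor_count is not None)
        if self.family == "none":
            if n_set > 1:
                raise ValueError("set at most one of bandwidth_h/neighbor_count")
            return
        if n_set != 1:
            raise ValueError("set exactly one of bandwidth_h or neighbor_count")
        if self.bandwidth_h is not None and self.bandwidth_h <= 0:
            raise ValueError("bandwidth_h must be > 0")

    def resolve_h(self, data, obs_index: int) -> float:
        if self.bandwidth_h is not None:
            return float(self.bandwidth_h)
        if self.neighbor_count is not None:
            return bandwidth_from_neighbors(data, obs_index, self.neighbor_count)
        return 1.0  # family "none": unused


@dataclass(frozen=True)
class Anchor:
    """A user move: observation ``obs_index`` dragged to ``latent_target``.

    The attractor centre defaults to the latent target (mu* = r*) and the
    attractor width to the model's shared basis width.
    """

    obs_index: int
    latent_target: np.ndarray
    attractor_center: np.ndarray | None = None
    attractor_width: float | None = None

    def __post_init__(self):
        t = np.asarray(self.latent_target, dtype=float).reshape(-1)
        if not np.all(np.isfinite(t)):
            raise ValueError("latent target must be finite")
        object.__setattr__(self, "latent_target", t)

    def center(self) -> np.ndarray:
        if self.attractor_center is None:
            return self.latent_target
        return np.asarray(self.attractor_center, dtype=float).reshape(-1)


@dataclass(frozen=True)
class InteractionRecord:
    obs_index: int
    latent_target: tuple[float, float]
    stage: int
    family: str
    bandwidth_h: float | None
    neighbor_count: int | None
    refit_iterations: int
    timestamp: str = ""


def bandwidth_from_neighbors(data, obs_index: int, m: int) -> float:
    """Distance from x* to its m-th nearest other observation."""
    X = as_values(data)
    N = X.shape[1]
    if not 0 <= obs_index < N:
        raise ValueError("obs_index out of range")
    if not 1 <= m <= N - 1:
        raise ValueError(f"neighbor count must be in [1, {N - 1}]")
    d = np.linalg.norm(X - X[:, obs_index][:, None], axis=0)
    d = np.delete(d, obs_index)
    d.sort()
    return float(d[m - 1])


def scaling_weights(data, anchor: Anchor, config: ScalingConfig) -> np.ndarray:
    """Per-observation multipliers V(Delta_i), Delta_i = ||x* - x_i|| / h."""
    X = as_values(data)
    if not 0 <= anchor.obs_index < X.shape[1]:
        raise ValueError("anchor observation index out of range")
    h = config.resolve_h(data, anchor.obs_index)
    if h <= 0:
        raise ValueError("bandwidth must be > 0")
    delta = np.linalg.norm(X - X[:, anchor.obs_index][:, None], axis=0) / h
    v = SCALING_FAMILIES[config.family](delta)
    return np.asarray(v, dtype=float)


def add_anchor(model: GTMModel, data, anchor: Anchor) -> GTMModel:
    """Expand the model with the anchor's latent point and attractor.

    J and K each grow by one; the new loading column starts at zero so the
    manifold is unchanged at iteration zero; the anchored observation's
    responsibility row is pinned to the new component in every later E-step.
    """
    X = as_values(data)
    if not 0 <= anchor.obs_index < X.shape[1]:
        raise ValueError("anchor observation index out of range")
    r_star = anchor.latent_target
    (x0, x1), (y0, y1) = model.lattice.extent
    if not (x0 <= r_star[0] <= x1 and y0 <= r_star[1] <= y1):
        warnings.warn("anchor target lies outside the lattice extent",
                      UserWarning, stacklevel=2)
    lattice = append_grid_point(model.lattice, r_star)
    basis = append_basis_center(model.basis, anchor.center())
    if anchor.attractor_width is not None and \
            anchor.attractor_width != model.basis.width:
        warnings.warn("attractor width differs from the shared basis width; "
                      "the shared width is used", UserWarning, stacklevel=2)
    W = np.hstack([model.W, np.zeros((model.W.shape[0], 1))])
    comp = AnchorComponent(obs_index=anchor.obs_index,
                           lattice_index=lattice.n_points - 1,
                           basis_index=basis.n_columns - 1,
                           weights=None)
    blend_layers = model.blend_layers
    if blend_layers:
        # keep the top blend layer in sync with the expanded parameterisation
        # (the zero column does not change its evaluation)
        top = replace(blend_layers[-1], W=W, basis=basis)
        blend_layers = blend_layers[:-1] + (top,)
    manifold = np.hstack([model.manifold,
                          manifold_at(model, r_star[:, None])])
    return replace(model, lattice=lattice, basis=basis, W=W,
                   manifold=manifold, anchors=model.anchors + (comp,),
                   blend_layers=blend_layers)


def _with_weights(model: GTMModel, anchor: Anchor,
                  weights: np.ndarray | None) -> GTMModel:
    """Attach scaling weights to the anchor component matching ``anchor``."""
    comps = list(model.anchors)
    for i in range(len(comps) - 1, -1, -1):
        if comps[i].obs_index == anchor.obs_index:
            comps[i] = replace(comps[i], weights=weights)
            return replace(model, anchors=tuple(comps))
    raise ValueError("model has no anchor component for this observation")


def scaled_e_step(model: GTMModel, data, anchor: Anchor,
                  weights: np.ndarray | None) -> np.ndarray:
    """E-step with the anchor component's locally scaled likelihood.

    The anchor component's kernel uses exponent -beta/2 V(Delta_i)
    ||x_i - y*||^2; all other components are unchanged; the anchored row
    stays pinned.  With V == 1 this reduces exactly to the plain E-step.
    """
    return core.e_step(_with_weights(model, anchor, weights), data)


def conditional_refit(model: GTMModel, data, anchor: Anchor,
                      weights: np.ndarray | None = None,
                      config: FitConfig | None = None) -> tuple[GTMModel, np.ndarray]:
    """EM re-estimation of W and beta with r* and mu* held fixed.

    Warm-starts from the current loadings; alternates the scaled E-step and
    the weighted M-step until the conditional objective's relative change
    drops below ``config.rel_tol``.  Returns the refit model (whose manifold
    is the user-adjusted surface y^(u)) and the objective trace.
    """
    config = config or FitConfig()
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0) or not np.all(np.isfinite(weights)):
            raise ValueError("scaling weights must be finite and nonnegative")
    model = _with_weights(model, anchor, weights)
    lls: list[float] = []
    prev = -np.inf
    for _ in range(config.max_iter):
        R = core.e_step(model, data)
        model = core.m_step(model, data, R, config)
        ll = core.log_likelihood(model, data)
        lls.append(ll)
        if np.isfinite(prev) and abs(ll - prev) <= config.rel_tol * abs(prev):
            break
        prev = ll
    return model, np.array(lls)


def mixing_weights(lattice, r_star: np.ndarray) -> tuple[np.ndarray, float]:
    """delta_j = ||r_j - r*|| / b with b = max_j ||r_j - r*||.

    Computed over every point of the (expanded) lattice, which guarantees
    delta in [0, 1] with the maximum attained exactly.
    """
    pts = lattice.points if isinstance(lattice, core.LatentGrid) else np.asarray(lattice, dtype=float)
    r_star = np.asarray(r_star, dtype=float).reshape(-1)
    d = np.linalg.norm(pts - r_star[:, None], axis=0)
    b = float(d.max())
    if b == 0.0:
        return np.zeros_like(d), 0.0
    return d / b, b


def blend_manifolds(current: np.ndarray, user_adjusted: np.ndarray,
                    lattice, r_star: np.ndarray) -> np.ndarray:
    """Convex per-column mixture of the pre-move and refit manifolds.

    Columns at delta = 1 (the farthest lattice point) are bit-identical to
    ``current``; the column at r* (delta = 0) equals ``user_adjusted``.
    """
    current = np.asarray(current, dtype=float)
    user_adjusted = np.asarray(user_adjusted, dtype=float)
    if current.shape != user_adjusted.shape:
        raise ValueError("manifold shapes differ")
    delta, b = mixing_weights(lattice, r_star)
    if b == 0.0:
        warnings.warn("all lattice points coincide with r*; returning the "
                      "user-adjusted manifold", RuntimeWarning, stacklevel=2)
        return user_adjusted.copy()
    out = delta[None, :] * current + (1.0 - delta)[None, :] * user_adjusted
    out[:, delta == 1.0] = current[:, delta == 1.0]
    out[:, delta == 0.0] = user_adjusted[:, delta == 0.0]
    return out


def move_point(model: GTMModel, data, obs_index: int, latent_target,
               scaling_config: ScalingConfig | None = None, stage: int = 3,
               config: FitConfig | None = None
               ) -> tuple[GTMModel, np.ndarray, np.ndarray, InteractionRecord]:
    """Execute one complete interaction and return the updated view.

    stage 1: anchor + conditional refit with V == 1;
    stage 2: anchor + conditional refit with the configured V weights;
    stage 3: stage 2 followed by manifold mixing with the pre-move surface,
    responsibilities and projections recomputed from the blend.
    Repeated calls compose: anchors accumulate and J, K grow by one each.
    Returns (model, posterior-mean coordinates, magnification factors,
    interaction record).
    """
    if stage not in (1, 2, 3):
        raise ValueError("stage must be 1, 2 or 3")
    scaling_config = scaling_config or ScalingConfig()
    config = config or FitConfig()
    anchor = Anchor(obs_index=obs_index, latent_target=np.asarray(latent_target, float))

    pre_model = model
    anchored = add_anchor(model, data, anchor)
    if stage == 1 or scaling_config.family == "none":
        weights = None
        h = None
    else:
        weights = scaling_weights(data, anchor, scaling_config)
        h = scaling_config.resolve_h(data, anchor.obs_index)
    refit, trace = conditional_refit(anchored, data, anchor, weights, config)

    if stage == 3:
        r_star = anchor.latent_target
        y_current = manifold_at(pre_model, refit.lattice.points)
        y_user = refit.manifold
        blended = blend_manifolds(y_current, y_user, refit.lattice, r_star)
        _, b = mixing_weights(refit.lattice, r_star)
        base = pre_model.blend_layers or (
            BlendLayer(W=pre_model.W, basis=pre_model.basis),)
        layers = base + (BlendLayer(W=refit.W, basis=refit.basis,
                                    r_star=r_star, b=b),)
        final = replace(refit, manifold=blended, blend_layers=layers)
    else:
        final = refit

    coords = core.project(final, data, "mean")
    mag = core.magnification(final)
    record = InteractionRecord(
        obs_index=obs_index,
        latent_target=(float(anchor.latent_target[0]),
                       float(anchor.latent_target[1])),
        stage=stage,
        family=scaling_config.family if stage > 1 else "none",
        bandwidth_h=h,
        neighbor_count=scaling_config.neighbor_count if stage > 1 else None,
        refit_iterations=len(trace),
    )
    return final, coords, mag, record


def replay(model: GTMModel, data, moves: Sequence[dict],
           config: FitConfig | None = None) -> tuple[GTMModel, list[InteractionRecord]]:
    """Apply a sequence of move records (as parsed from a JSONL script).

    Each record carries obs_index (or obs_id resolved by the caller),
    target [a, b], and optionally stage, family, h or neighbors.  Replaying
    the same script on the same model/data is deterministic.
    """
    records = []
    for mv in moves:
        family = mv.get("family", "delta3")
        if "h" in mv and mv["h"] is not None:
            sc = ScalingConfig(family=family, bandwidth_h=float(mv["h"]))
        elif "neighbors" in mv and mv["neighbors"] is not None:
            sc = ScalingConfig(family=family, neighbor_count=int(mv["neighbors"]))
        elif family == "none":
            sc = ScalingConfig(family="none")
        else:
            raise ValueError("move record needs 'h' or 'neighbors'")
        stage = int(mv.get("stage", 3))
        fc = config
        if "refit_max_iter" in mv and mv["refit_max_iter"] is not None:
            fc = replace(config or FitConfig(), max_iter=int(mv["refit_max_iter"]))
        model, _, _, rec = move_point(model, data, int(mv["obs_index"]),
                                      np.asarray(mv["target"], float),
                                      sc, stage, fc)
        records.append(rec)
    return model, records
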