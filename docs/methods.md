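# Methods

This note records the model, the defaults, and the design choices made
where the method itself leaves the implementation open.

## The base model

GTM models a p×N data matrix x as an equal-weight mixture of J isotropic
Gaussians whose means are constrained to a smooth surface: y_j = W Φ(r_j),
with r_j a regular 2-D lattice over [−1,1]², Φ a bank of K Gaussian kernels
of shared width σ², and precision β shared by all components. The E-step
computes responsibilities R_ij ∝ exp(−β/2 ‖x_i − y_j‖²) (the (β/2π)^{p/2}
prefactor cancels; rows are normalised after a max-shift so extreme β cannot
overflow). The M-step solves the weighted normal equations
(Φᵀ G Φ + λI) Wᵀ = Φᵀ R Xᵀ with G = diag(colsums R), then updates
β⁻¹ = Σ_ij R_ij ‖x_i − y_j‖² / (Np). The log-likelihood
Σ_i log((1/J) Σ_j p(x_i|y_j,β)) is evaluated in log space.

**Assumptions.** Isotropic, homoscedastic noise; a genuinely 2-D intrinsic
structure (q is fixed at 2); no missing entries. Because the default basis
has no bias column, the manifold lives in the span of W's columns: data far
from the origin is handled by EM (the kernels can synthesise a near-constant
offset inside the lattice), but the *initialisation* is exact only for data
whose principal plane passes through the origin. Centering data first is
harmless and slightly improves the first few iterations.

## Defaults and why

| parameter | default | rationale |
|---|---|---|
| lattice | 20×20 on [−1,1]² (J=400) | reference configuration for desk-scale data; resolution of the view |
| basis | 4×4 (K=16), σ = 1 × center spacing | kernels overlap enough to cover the latent square smoothly |
| bias column | off | plain kernel bank; a constant column is available via `has_bias` |
| ridge | 1e-6 | J≫K normal equations can be ill-conditioned; negligible bias otherwise |
| convergence | rel. log-likelihood change < 1e-5, ≤ 200 iterations | deterministic desk-scale stopping; non-convergence is reported, not raised |
| init | PCA (deterministic eigenvector signs) | standard GTM practice; β⁻¹ starts at max((q+1)-th eigenvalue, half squared manifold spacing) |
| mode-projection ties | lowest lattice index | reproducibility |

## Interaction machinery

Anchoring appends r\* to the lattice and an attractor at μ\* = r\* (same σ²
as the basis) to Φ; the new loading column starts at **zero**, so the
manifold is unchanged before the conditional refit, and the moved
observation's responsibility row is pinned to the new component in every
later E-step. The conditional refit is EM with r\*, μ\* held fixed; it
warm-starts from the current loadings. The scaled density
exp(−β/2 V(Δ_i) ‖x_i − y\*‖²) is used wherever the anchor component's
density appears — E-step, W update (effective weight R_ij·V_i) and β update
— so the refit is coordinate ascent on one consistent objective and its
trace is non-decreasing. V(0) is defined as 0 for the exponential families
by continuity (the power families vanish at 0 naturally): the moved
observation itself is maximally attracted. The unnormalised prefactor is
kept unchanged under scaling; it cancels in responsibilities.

The stage-3 blend y_j ← δ_j y^(c)_j + (1−δ_j) y^(u)_j uses
δ_j = ‖r_j − r\*‖/b with b the maximum over *all* points of the expanded
lattice — the only reading that guarantees δ ∈ [0,1] with the maximum
attained. Columns at δ=1 are copied verbatim (bit-identical), the column at
r\* is the refit one. Blending is applied once per completed move; a smooth
animation can be emulated by replaying a move as a sequence of waypoints.
Because a blended manifold no longer factors as W Φ, the model stores the
blend recursion (each layer's W, basis, r\*, b) and evaluates the manifold
at arbitrary latent points by folding the layers; sequential moves and
tagging therefore compose exactly, and magnification for blended models
falls back to central finite differences of that evaluation (the analytic
Jacobian applies only to the pure W Φ form).

**Bandwidth.** h can be given directly or derived as the distance from x\*
to its m-th nearest observation ("at least m matches follow"). For the
five-cluster testbed, the behavioural demonstrations use V = Δ³ with
h = 20: the bandwidth must be on the scale of the *between-group*
separation (≈ 24 here) for a whole cluster to follow; a within-cluster
bandwidth produces V·‖x_i − y\*‖² values so large that no observation ever
gains responsibility at the anchor, and nothing moves.

**What an in-place anchor does.** The added attractor is a full mixture
component and competes for neighbouring observations' responsibility, so
anchoring an observation at its current position is *not* an exact fixed
point of the refit — the manifold drifts measurably. The guaranteed
properties are the monotone conditional objective, the pinned projection,
and stage-3 locality; the in-place anchor merely perturbs the view less
than a genuine drag.

## Text features

ImpI_i = Σ_jΣ_k |f_ij − f_ik| / (2N²μ_i) with μ_i the mean frequency of
term i — a Gini-style dispersion index: 0 for uniformly spread terms,
maximal for single-document terms. With the N² denominator (dialect
`printed`, the default) the single-document endpoint is (N−1)/N; the
sample-corrected denominator 2N(N−1)μ_i (dialect `corrected`) makes it
exactly 1, consistent with the statistic's stated [0,1] range. Both
dialects are computed by the same double-sum path; tests cross-check
against an independent sort-based order-statistic form.

The weighted feature is f\*_ij = ImpI_i · f_ij · F / (‖d_j‖‖e_i‖) — the
observed/expected lift of the cell scaled by the term's importance — where
‖d_j‖, ‖e_i‖, F are the document, term and grand totals. The printed form
of this expression is typographically ambiguous; the alternative grouping
ImpI·f/(‖d‖‖e‖F) is available via `reading="scaled"`. Zero counts always
map to zero.

Preprocessing lowercases, tokenises on non-letter boundaries, removes a
standard English stopword list (shipped as package data) and applies a
Porter suffix stemmer implemented in `gtmview._stem`. Tagging evaluates
y⁺ = W Φ(r⁺) (through any blend layers) and reports the top-m terms
(default m = 10, ties lexicographic). Cluster keywords run k-means
(Lloyd's, 10 restarts, fixed seed) on the 2-D coordinates, rank terms per
cluster by the summed ImpI-weighted vectors of member documents, and pull
out terms present in every cluster's list as "shared".

## Synthetic data

`simulate_clusters` draws 50 points per cluster from five unit-variance
isotropic Gaussians in 3-D at centers (−7,−7,−7), (−7,−1,−7), (−1,−7,−7)
and (7,7,7), (7,1,7): two groups in opposite corners, nearest inter-center
distance exactly 6σ. It emulates the qualitative geometry of the classic
topographic-recovery testbed; it does not model anisotropy, outliers or
unequal cluster sizes, so passing the recovery check says the map preserves
*well-separated* structure, not that it resolves subtle substructure.

`synthetic_corpus` plants 4 topics × 15 documents × 10 topic terms over a
60-term background: topic terms ~ Poisson(8) in their own documents and
absent elsewhere, background ~ Poisson(1) everywhere. Only count structure
is modelled — no word order, synonymy or topic overlap — so keyword/tag
recovery on it demonstrates the mechanics of the pipeline, not performance
on real abstracts.

## Numerical notes and limitations

- All randomness flows through `numpy.random.default_rng(seed)`; fits, moves
  and generators are bit-reproducible, and replaying an interaction log
  reproduces the final model exactly.
- Degenerate cases: a row of equal distances yields a uniform responsibility
  row; singular M-step equations raise with advice to increase the ridge;
  a zero-distance lattice (all points at r\*) makes the blend return the
  refit manifold with a warning; rank-deficient Jacobians report factor 0
  with a warning.
- Problem sizes throughout the tests (N = 250 observations, J = 400, K = 16;
  60-document corpora) are desk-scale choices that keep every check
  comfortably interactive.
- Not covered: 3-D latent spaces, missing-data EM, dragging several points
  in one move, and any inferential/uncertainty statement about a view —
  the tool supports exploration, not testing.
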