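# Methods

## Model

Observed variables X ∈ ℝ^p and latent variables Z ∈ ℝ^r (r ≪ p) are jointly
Gaussian with precision matrix Ω_{(X,Z)}. Marginalizing Z gives the observed
precision Σ_X⁻¹ = Ω_X − Ω_{XZ} Ω_Z⁻¹ Ω_{ZX} = Ω − L: a sparse matrix Ω (the
conditional-independence network among observed variables) minus a PSD matrix
L of rank ≤ r (the latent contribution). Given a sample covariance S from n
observations, the estimator solves

    min_{Ω − L ≻ 0, L ⪰ 0}  Tr S(Ω − L) − log det(Ω − L)
                            + λ₁ P₁(Ω) + λ₂ P₂(L)

with either the concave pair P₁(Ω) = Σ|ω_ij|^½, P₂(L) = Σ√σ_i(L)
(`family="half"`) or the convex pair ‖Ω‖₁, ‖L‖_* (`family="convex"`, the
classical latent-variable graphical lasso; with λ₂ = 0 and L = 0 it reduces
further to the graphical lasso). The concave penalties are bridge (ℓ_q,
q = 1/2) penalties; they do not require the irrepresentable condition and
shrink large coefficients much less than ℓ₁, at the cost of nonconvexity.

The k-condition joint model adds, per consecutive pair of conditions, a
fused concave term λ₃ Σ|ω^{(i+1)}_{jl} − ω^{(i)}_{jl}|^½ coupling the sparse
parts along a chain (1,2), (2,3), …. Chain coupling matches the temporal
reading of multi-stage data; all-pairs coupling is deliberately not
implemented. Two conditions are the primary, tested case.

## Proximity operators

All three penalties have exact proxes built from the scalar
*half-thresholding* operator, prox of λ|x|^½:

- zero whenever |y| ≤ T(λ) = (3/2)λ^{2/3} — at the exact tie |y| = T(λ) both
  branches attain the same objective (at λ = 1: both equal 1.125 at
  y = 1.5) and the sparser minimizer 0 is returned;
- above the threshold, the trigonometric closed form
  sign(y)·(2/3)|y|(1 + cos(2π/3 − (2/3)arccos((λ/4)(|y|/3)^{−3/2}))),
  equal to u² for u the largest root of u³ − |y|u + λ/2 = 0. The operator is
  odd and discontinuous at the threshold (it jumps to (2/3)T(λ)); it is not
  nonexpansive, which is inherent to concave penalties.

Matrix versions: entrywise with an optional penalization mask; on eigenvalues
of a symmetric matrix for the singular-value penalty (eigendecomposition
rather than a general SVD — exact for symmetric input, sign-consistent, and
cheaper; inputs with asymmetry above 1e−8 trigger a warning before
symmetrization), with optional projection onto the PSD cone for the L block.
The fused pair prox reduces by a mean/difference change of variables: the
pair mean is preserved exactly and the difference is half-thresholded **at
weight 2λ** (the quadratic in the difference variable carries a factor 1/4).
A first-order stationarity check and a 2-D brute-force grid oracle both
confirm the factor 2; the test suite pins it.

## Solver

A consensus variable X = Ω − L splits the objective. The augmented
Lagrangian (weight ρ) is minimized block-by-block in Gauss–Seidel order
X → Ω → L, followed by dual ascent on Y and a momentum blend:

1. X ← eigendecomposition-based log-det resolvent of
   B = ρ(Ω − L) − Y − S; output eigenvalues (d + √(d² + 4ρ))/(2ρ) are
   strictly positive, so X is PD by construction at every sweep.
2. Ω ← sparse prox of X + L + Y/ρ at level λ₁/ρ.
3. L ← singular-value prox of Ω − X − Y/ρ at level λ₂/ρ with PSD
   projection, so L is PSD at every sweep.
4. Y ← Y − ρ(Ω − L − X).
5. Momentum: α_{k+1} = (1 + √(1 + 4α_k²))/2, γ_k = (α_k − 1)/α_{k+1}
   (α₁ = 1), and the damped blend ω^{k+1} = (1 − γ)ω^k + γω̂. Because
   γ₁ = 0, the verbatim blend makes no progress on the first sweep; the
   default `momentum="accelerated"` takes the plain step ω̂ whenever γ = 0
   and the damped blend otherwise. `"literal"` applies the verbatim rule
   (documented as non-progressing at step 1), `"off"` disables blending.
   The blend is a convex combination, so PD of X and PSD of L survive it.

Defaults: ρ = 1 fixed (no adaptive scheme, keeping the contraction
diagnostics interpretable), initialization X = Ω = I, L = 0, Y = 0,
tol_primal = 1e−5 on ‖Ω − L − X‖_F, tol_change = 1e−6 relative, max_iter =
500, support threshold 1e−6 on |ω_ij|. Non-convergence is reported via
`converged=False` with the full residual trace, never an exception.

With concave penalties only local convergence is claimed. The accompanying
contraction certificate is the 4×4-block matrix H (identity diagonal blocks,
couplings of magnitude 1/2 between the dual block and each primal block)
whose smallest eigenvalue is (2 − √3)/2; the per-iteration contraction
coefficient (γ − 2 + √3)γ is positive once γ_k > 2 − √3 ≈ 0.268 (from the
second sweep on). The sign pattern of the ±1/2 couplings does not affect the
spectrum (the coupling vector always has norm √3/2); all +1/2 is used. As an
empirical surrogate for the contraction property the solver records the full
iterate history on request, and the tests assert that the distance to the
final iterate is nonincreasing (1e−6 slack) once γ_k has crossed 2 − √3.

The joint solver duplicates the blocks per condition and adds, per coupled
pair, copy variables (Z_i, Z_j) of the two sparse parts with their own
duals, updated by the exact fused prox; the Ω_i update averages the
quadratic pulls of its consensus and copy constraints and applies the
sparse prox at level λ₁/(mρ) for m pulls. Each prox is applied exactly once
per sweep — a local-convergence heuristic, consistent with the
single-condition claims. Pairs with λ₃ = 0 are not instantiated: the
objective decouples exactly, and the joint fit provably coincides with
independent fits.

## Tuning

BIC(λ₁, λ₂) = −2[log det(Ω − L) − Tr S(Ω − L)] + γ·k·log n, with k the
number of nonzero entries of Ω (default: all entries above 1e−6; the rank of
L is deliberately not counted — a known limitation) and γ = 1 by default.
The deviance term is the single-observation form without a sample-size
multiplier, so the complexity term dominates and the criterion acts as a
parsimony screen *within* a grid that brackets the interesting support
regime, not as an asymptotically consistent selector. A literal-sign audit
variant (deviance term flipped, which rewards poor fit) is available behind
`literal_sign` and never used by default.

Default screening grids (chosen for the synthetic benchmark scale, where
true partial correlations are of order 0.1): λ₁ ∈ geomspace(0.002, 0.01, 5)
— below the lower end supports saturate, above the upper end the concave
local solutions collapse toward empty supports — and
λ₂ ∈ geomspace(0.05, 0.8, 5), spanning latent ranks from r down to 0. The
grid is traversed row-major in increasing order with warm starts from the
previous grid point; nonconvexity makes results path-dependent, so the path
is fixed and part of the protocol. Warm starts matter: they roughly double
the BIC-selected MCC at n = 4p compared with cold starts.

Edge confidence: the sparsity weight λ₁ (first condition's weight in the
joint model) is multiplied by Uniform(1 − f, 1 + f) draws (f = 0.5 by
default, seeded), the model is refitted per draw, and each edge's appearance
frequency is reported; the consensus network keeps edges with frequency ≥
keep_frac (0.75 under 1000 draws in the two-stage workflow; an optional
tie ratio sets the second condition's λ₁ to 0.8× the perturbed value). The
perturbation law is a design choice — the procedure it supports only needs
a seeded, symmetric-around-1 jitter.

## Synthetic generator

The generator reproduces the standard benchmark: exactly round(density·p²)
template positions drawn uniformly without replacement in a p×p template
(density 0.05, i.e. 125 positions at p = 50), filled with N(0, σ² = 3)
draws, symmetrized as T + Tᵀ, then 1.1·I added repeatedly until the smallest
eigenvalue is positive (the diagonal typically ends near 9.9 at p = 50).
Exact-count placement keeps the planted fraction testable. A random
latent_frac = 0.1 of the variables is marginalized out: the observed
covariance is the true marginal (Ω⁻¹)_OO, whose inverse is the Schur
complement Ω_OO − Ω_OH Ω_HH⁻¹ Ω_HO — the identity is validated to 1e−8 on
every generated problem. A `subblock` audit mode inverts the precision
subblock directly instead; it produces no low-rank component and exists only
to quantify the difference between the two readings of the protocol.
Sampling draws n i.i.d. zero-mean Gaussians through a Cholesky factor and
uses the 1/n second-moment covariance (mean known to be zero; centering
optional). Sample sizes of interest are n ∈ {p/2, p, 2p, 4p} relative to the
observed dimension.

What the generator does *not* emulate about real expression data:
non-Gaussian marginals, heteroscedastic technical noise, batch structure,
and hub-dominated degree distributions. Passing the synthetic suite
therefore demonstrates correctness of the estimator and protocol, not
robustness to those violations. A simple edge-rewiring perturbation is
provided to build related condition pairs for joint-model tests; it is
plumbing, not a model of network evolution.

## Evaluation

Support metrics use the off-diagonal upper triangle only. MCC =
(tp·tn − fp·fn)/√((tp+fp)(tp+fn)(tn+fp)(tn+fn)), defined as 0 when any
factor vanishes. Estimation error is the spectral norm ‖S(Ω − L) − I‖₂.
The rescaled sample size n/((s + r)·log p) uses the natural logarithm.
At benchmark conditions (p = 50, 45 observed, BIC-tuned λ over the default
5×5 grid, five replicates), the median MCC is ≈0.12/0.19/0.29/0.43 at
n = p/2, p, 2p, 4p — monotone in n; these numbers are recomputed, not
stored, by `scripts/acceptance.py` and the acceptance tests.

## Problem sizes and numerical choices

The shipped experiments use p = 50 with 45 observed variables, 5 × 5 tuning
grids and 5 replicates per sample size — sizes chosen so the whole
evaluation runs in minutes on one core while still exercising the p ≫ n
regime the method targets. PD/PSD tolerances: eigenvalues above −1e−8 count
as PSD (clipped); asymmetry above 1e−8 is an error for covariances and a
warning (then forced symmetrization) for prox inputs. The convex mode is
cross-checked against an independent plain-ADMM reference implementation
(tests/reference_convex.py) — the convex problem has a unique optimum, so
agreement in objective value to 1e−5 is a meaningful correctness check; for
checks with entrywise 1e−6 contracts (the large-λ₃ fusion limit) the solver
is run at tighter tolerances than its defaults, since the contract is on the
result, not the stopping rule.

## Known limitations

- Concave objectives: only stationary points are found; results depend on
  initialization and (in grid search) on the warm-start path, which is why
  both are fixed.
- The BIC's missing sample-size multiplier makes it a parsimony screen; the
  grid bounds are part of the protocol.
- The fused joint update is a heuristic splitting (each prox once per
  sweep); no global statement is made for k > 2 or all-pairs coupling.
- The rank of L is not penalized in the BIC's complexity count.
- Real-data ingestion supports TSV/CSV expression matrices only; no
  accession download or platform-specific preprocessing.
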