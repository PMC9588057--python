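# Methods

## The model space

A functional brain network observed through fMRI/EEG/MEG is commonly
summarized by an n×n correlation matrix over regions or channels. The set of
full-rank correlation matrices (the *elliptope*)

C⁺⁺ⁿ = { C : C = Cᵀ, C ≻ 0, diag(C) = 1 }

is a strict subset of the SPD cone and has dimension n(n−1)/2. Treating
correlation matrices directly as SPD points is convenient but incoherent:
SPD operations (Fréchet means, exponentials) leave the unit-diagonal set, so
a post-hoc renormalization is needed at every step. This package instead
works in the quotient geometry: the group D⁺⁺ⁿ of positive diagonal matrices
acts on the SPD manifold by congruence Σ ↦ DΣD, the action is smooth, proper
and free, and the quotient S⁺⁺ⁿ/D⁺⁺ⁿ is identified with C⁺⁺ⁿ through the
invariant submersion

Π(Σ) = diag(Σ)^{−1/2} Σ diag(Σ)^{−1/2}.

The ambient metric is the affine-invariant Riemannian metric (AIRM),
d(A,B) = ‖logm(A^{−1/2} B A^{−1/2})‖_F, which is invariant under the group
action and therefore descends to the quotient:

d_corr(C₁, C₂) = min over positive diagonal D of d_AIRM(C₁, D C₂ D).

All downstream algorithms consume only four primitives: the distance above,
the horizontal-lift logarithm log_{C₁}(D* C₂ D*) at the minimizer D*, the
exponential Π(exp^{AIRM}_C(V)) — which lands exactly on the unit diagonal by
construction — and pairwise/batched variants of these. The same interface is
implemented for the ambient AIRM ("spd") and the Frobenius baseline
("euclidean"), selected by a `GeometrySpec`, so every analysis can be run
under all three geometries without code changes.

## Fiber optimization

The inner problem min_D d²(C₁, D C₂ D) is parametrized by x = log diag(D)
(unconstrained, x = 0 the canonical representative). With A = C₁^{−1/2} and
M(x) = A D C₂ D A, the objective is f(x) = ‖logm M‖²_F and the gradient is
exact:

∂f/∂x_k = 4 d_k (A G A D C₂)_{kk},  G = M^{−1} logm M,

using that G commutes with M so the Fréchet derivative of the log collapses
inside the trace. The solver is a damped Newton iteration — exact gradient,
central-difference Hessian (step 1e−5), Levenberg damping, Armijo
backtracking with an absolute slack of 1e−12·max(1,|f|) so that predicted
decreases below rounding noise still accept, and steps capped at ∞-norm 20
in the log domain so trial points keep exp(x) representable — stopping when the gradient
∞-norm falls below 1e−9 or after 100 iterations (warned and flagged). The
same code path runs *batched* over stacks of pairs (all matrix work via
stacked `eigh`/`einsum`), which is what makes distance matrices, Fréchet
means and the permutation studies cheap: a full 60×60 geodesic distance
matrix of 5×5 matrices takes ~0.2 s on one core.

By affine invariance d(C₁, D C₂ D) = d(D^{−1} C₁ D^{−1}, C₂), the problem is
direction-symmetric; each unordered pair is solved once, so distance
matrices are exactly symmetric. On 2×2 problems the solver agrees with an
exhaustive grid search over the fiber to the grid resolution and with a
derivative-free local refinement to ~1e−15 (see `scripts/acceptance.py`).

All matrix functions of symmetric matrices (sqrtm, logm, expm, powers) use
symmetric eigendecomposition, never series expansions. Validity checks:
symmetry within 1e−10, eigenvalues > 1e−12 for SPD, unit diagonal within
1e−12 and smallest eigenvalue ≥ 1e−10 for correlation matrices (near-singular
matrices are rejected — the quotient construction needs full rank).

## Central tendency

The L_p center of mass minimizes f(μ) = (1/N) Σ dᵖ(μ, C_i); the attained
value is the sample variation V_p. For p = 2 (Fréchet mean) we iterate the
Karcher step μ ← exp_μ(τ · mean_i log_μ C_i) with τ = 1, halving τ whenever
the cost would increase; for p = 1 (median) the Riemannian Weiszfeld update
weights each log by 1/(d_i + δ), δ = 1e−12 guarding against an iterate
coinciding with a data point, again with step halving so the cost trace is
non-increasing. Both start from the submersed Euclidean average (cheap,
in-manifold, close to the optimum for concentrated data) and stop when the
Frobenius increment between iterates falls below ε (default 1e−8, max 200
iterations); a small increment certifies a small averaged gradient. Every
iterate under the correlation geometry has an exactly unit diagonal.

## Clustering

*k-means* is intrinsic Lloyd: nearest-centroid assignment under the geodesic
distance (ties broken randomly by seed), centroid update by the cluster
Fréchet mean (inner tolerance 1e−7). Centroids are seeded at data points by
greedy distance-proportional sampling with 4 seeded restarts, keeping the
partition of lowest within-cluster sum of squared distances; a uniformly
seeded start merges balanced classes too often for an exact-recovery
guarantee to hold across seeds. Emptied clusters are re-seeded with the
observation farthest from the stale centroid.

*k-medoids* runs on a precomputed distance matrix: PAM's deterministic
greedy BUILD initialization, then alternation of nearest-medoid assignment
and replacement of each medoid by the cluster member of minimal average
dissimilarity. Its objective (total within-cluster dissimilarity) is
monotone non-increasing.

*Spectral clustering* uses the self-tuning affinity
S_ij = exp(−d²_ij/(σ_i σ_j)) with σ_i the distance to the 7th nearest
neighbor (self excluded; 7 is the classic self-tuning default), the
normalized symmetric Laplacian L = D^{−1/2} S D^{−1/2}, the K eigenvectors of
the *largest* eigenvalues of L (the informative ones for this similarity
form; the smallest belong to I − L), row normalization, and Euclidean
k-means on the rows (scikit-learn). Distances below 1e−7·(1+max) are snapped
to zero so numerically identical observations behave as coincident points.

Validity indices use geodesic quantities throughout: the silhouette score
from the distance matrix (singletons score 0), and a Calinski–Harabasz index
whose separation/cohesion terms use squared geodesic distances to per-class
and global Fréchet means. Zero cohesion (duplicated groups) returns a large
sentinel with a warning rather than ∞.

## Embeddings

*Classical MDS* eigendecomposes the doubly centered matrix
B = −½ J D⁽²⁾ J; coordinates are the top-p eigenvectors scaled by √λ.
Negative eigenvalues — present exactly when the geodesic distances are not
Euclidean-realizable — are dropped, and their total magnitude is reported as
a non-Euclideanity diagnostic; the normalized strain is reported as a
diagnostic as well (the unnormalized minimizer is identical).

*Metric MDS* minimizes raw stress Σ_{i≠j}(D_ij − ‖X_i−X_j‖)² by SMACOF
(Guttman transform, unit weights), initialized from the classical-MDS
solution and centered first (stress is translation-invariant). Majorization
makes the stress trace non-increasing by construction; iteration stops at a
relative stress change below 1e−9 or 500 iterations.

*PGA* log-maps the data at the Fréchet mean and performs PCA in tangent
coordinates orthonormal under the affine-invariant inner product: the lifts
are whitened (Ĉ^{−1/2} U Ĉ^{−1/2}) and vectorized over the upper triangle
with off-diagonals ×√2, so the empirical covariance uses the metric at the
mean rather than raw matrix entries. Scores of the mean itself are exactly
zero; explained-variance fractions are eigenvalue shares of the total
tangent variance. The principal directions mapped through exp are geodesics
through the mean — an approximate, not orthogonal, basis away from it.

## Two-sample testing

Both statistics are functions of the pooled pairwise distance matrix, so a
permutation test shuffles labels without re-solving any fiber problem.

* Biswas–Ghosh: with mFF, mGG the mean within-sample and mFG the mean
  between-sample distances, T = (mFF − mFG)² + (mGG − mFG)².
* Wasserstein: the order-2 Wasserstein distance between the two empirical
  measures with geodesic ground cost, computed by exact discrete optimal
  transport — a linear assignment for equal sample sizes (the optimal plan
  between equal-size uniform measures is a matching), the transport LP
  (HiGHS) otherwise.

The Monte-Carlo permutation test samples label assignments uniformly with
replacement, seeded, and reports p = (1 + #{T_b ≥ T_obs})/(B + 1): never
zero, ties counted toward rejection (conservative).

## Synthetic data

Two generating processes are emulated. (a) Sample correlation matrices of
m = 50 i.i.d. draws from N(0, I₅), 20 matrices per replicate — sampling
noise around the identity, used for the mean-error comparison across
geometries. (b) Tangent perturbations of a model matrix: noise with i.i.d.
N(0, sd²) coordinates in a metric-orthonormal tangent basis at the model
(the same whitened coordinates as PGA — "tangent noise sd" is
metric-relative, and one convention is used everywhere), mapped through the
manifold exponential, so every sample is a valid full-rank correlation
matrix by construction.

Because empirically derived connectivity model matrices are not available
here, multi-class designs use synthetic stand-ins: random tangent directions
at the identity scaled until all pairwise geodesic distances clear a
threshold (`make_separated_models`), or submersed Wishart draws with a
smallest-eigenvalue floor (`random_model_corr`). The three-class study uses
3 models at pairwise distance ≥ 3 with 30 samples per class at sd = 0.3 —
a separation-to-noise ratio of ~10, at which exact recovery (ARI = 1) by
all three clustering algorithms is the expected behavior. The calibration
study uses two samples of 30 from one model (200 replicates, B = 200
permutations) and the power study two separated models (100 replicates).

What the generators do **not** emulate: temporal autocorrelation and
nonstationarity of real recordings, heavier-tailed signal distributions,
rank deficiency from short scans, and measurement artifacts. Passing tests
therefore certify the geometry and the algorithms, not robustness to
real-data pathologies; on real connectivity data the class structure is far
less separated than in the three-class design.

## Problem sizes and numerical choices

Simulation studies run at desk scale, chosen so the full suite completes in
a few minutes on one core: 50 replicates for the mean-error comparison,
90 matrices (5×5) for clustering/embedding, 200 null + 100 alternative
replicates at B = 200 for the tests. Key defaults: fiber tolerance 1e−9
(gradient ∞-norm), 100 inner iterations; mean/median ε = 1e−8, 200 outer
iterations; SMACOF tol 1e−9, 500 iterations; spectral knn = 7. Degenerate
inputs are handled explicitly: empty data and K out of range raise;
duplicated observations give zero distances (snapped), zero PGA eigenvalues,
silhouette 1 / CH sentinel; an exp of a tangent vector with Frobenius norm
beyond 1e8 raises an overflow error naming the norm.

## Known limitations

* The fiber problem is solved numerically; no global-optimality certificate
  exists for n > 2 (the 2×2 case is verified against exhaustive search).
  In practice the Newton iteration from x = 0 converges to the same minimum
  as grid search and is insensitive to permutation of variables.
* Geodesic computations scale as O(N²) fiber solves per distance matrix;
  n in the tens is comfortable, hundreds of matrices are fine, but very
  large N calls for subsampling or landmark methods.
* The correlation-geometry Fréchet mean is slower than its SPD counterpart
  (each iteration solves N fiber problems); the batched solver keeps this
  practical at study scales.
* PGA uses the full symmetric tangent coordinates; for the correlation
  geometry the ~n directions normal to the horizontal space carry
  (numerically) zero variance and are simply never selected.
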