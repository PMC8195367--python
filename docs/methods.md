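# Methods

## Model and solver

The package factors a gene × miRNA × cancer correlation tensor
A ∈ R^{p×q×M} into sparse rank-1 components. One component maximizes
the trilinear form Σ_k w_k (uᵀA_k v) over unit vectors with ℓ0 budgets
k_u, k_v, k_w. With two factors fixed the third has a closed-form
optimum: the k-sparse projection of its score vector, normalized
(Π(z, k)/‖Π(z, k)‖₂, where Π keeps the k largest-magnitude entries).
Block-coordinate ascent over (u, v, w) is therefore monotone in the
objective and converges to a fixed point; the objective value there,
d = Σ_k w_k (uᵀA_k v), is the component's singular value and is
nonnegative by construction, because the final w-update aligns w with
its score vector (d = ‖Π(z_w, k_w)‖₂). Components are extracted
sequentially by deflation, A ← A − d·(u∘v∘w), so the fitted terms plus
the residual reconstruct the input exactly (the telescoping identity is
asserted at 1e-10 in tests). The single-matrix sparse CCA baseline is
the M = 1, k_w = 1 special case of the same solver.

### Scaling of the tensor

The tensor's slices are X_kᵀY_k / (n_k − 1) on column-standardized
data — exact sample Pearson correlations — rather than the plain
cross-product X_kᵀY_k. Cohort sizes differ widely across cancers, and
the unscaled convention would let large cohorts dominate every module;
correlations keep slices comparable and match the modularity score's
use of correlation entries. `build_correlation_tensor(..., scale=False)`
restores the unscaled convention when wanted.

### Initialization and restarts

The classical start is w uniform (1/√M, …) with (u, v) the leading
singular pair of C = Σ_k w_k A_k, computed here with LAPACK's dense SVD
(deterministic; the matrix is small once p, q are at expression scale).
That start has a blind spot this package treats as first-class: when a
module's correlations flip sign across its cancers — which is exactly
the structure of sign-opposite co-expression, and of the default
synthetic protocol — the module cancels out of the uniform-w average
and the SVD start sees only noise. The default `init="slices"`
therefore also starts once from each w = e_k (every run carried to
convergence, best objective kept), which costs M extra fits and makes
sign-opposite modules reliably reachable. `init="svd"` restores the
bare classical start; `restarts=n` adds n seeded random starting
triples (a seed is then required — unseeded nondeterminism is treated
as an error throughout).

### Convergence, gauge, ties, degeneracy

- Stopping: max-norm change of u, v and w below `tol` (default 1e-6),
  or `max_iter` (default 1000) sweeps; non-convergence is recorded on
  the module, not raised. On realistic inputs convergence takes a few
  to ~20 sweeps.
- Gauge: (u, v) may be jointly negated without changing anything, so
  the solver flips them so the largest-|·| entry of v is positive.
  After that, a joint (u, w) sign freedom remains — it is data-resolved
  and documented, not forced, because w's sign pattern (which cancers
  correlate positively vs negatively with the module) is biologically
  meaningful and must not be normalized away.
- Ties in Π are broken toward the lowest index via a stable sort, so
  runs are bit-reproducible.
- A score vector that is exactly zero raises a degenerate-input error
  instead of silently re-randomizing; callers can enable seeded
  restarts. If the deflated residual degenerates before r modules are
  found, the modules found so far are returned with a warning.
- The objective trace (optional) records the feasible ascent: the
  dense SVD initialization is infeasible under the ℓ0 budgets, so
  recording starts at the first fully-constrained triple; from there
  every per-update value is non-decreasing (asserted at 1e-12 slack).

### Default sparsity

Defaults for expression-scale runs are k_u = 100 genes, k_v = 10
miRNAs, k_w = 20 cancers — the typical module size this method is
designed to report — all overridable per run.

## Statistics on modules

- **Modularity** of (I, J, K): mean |C_ijk| over the sub-tensor, in
  [0, 1] for correlation tensors. Significance is assessed against
  size-matched modules drawn uniformly without replacement from the
  axes; the permutation p is the add-one estimator
  (1 + #{null ≥ obs})/(1 + n_perm), which cannot be zero and is mildly
  conservative. Family-wise control across r modules is explicit
  Bonferroni (α/r, configurable family size).
- **Basic modularity**: the whole-slice mean |C| per cancer, the
  baseline a module's score should clearly exceed.
- **Co-expression modularity**: mean |pairwise correlation| among a
  module's genes (or miRNAs) within one cancer's expression, with the
  same resampling null over features.
- **Module overlap**: pooled shared elements across the three axes,
  with per-axis counts reported; the null resamples both supports
  uniformly with sizes fixed. On a single axis this null is exactly
  hypergeometric, which the tests exploit as an oracle. Note the
  statistic is integer-valued: for very small supports the add-one p
  is conservative purely through ties.
- **Hypergeometric enrichment**: right tail P(X ≥ overlap) with the
  background restricted to the analysis universe (all genes/miRNAs
  that entered the tensor) by default; members outside the background
  are an error rather than a silent background inflation.
- **Edge enrichment**: hypergeometric on within-set edge counts, with
  draws = member pairs and population = background pairs (unordered
  gene pairs, or ordered miRNA × gene pairs). The degree-aware variant
  replaces the analytic null with permutations that resample each
  member from its degree bin (default 10 logarithmically spaced bins;
  empty bins fall back to the nearest nonempty one, noted on the
  result). Degree-binned resampling was chosen over edge rewiring for
  speed and because it keeps the member-set size and degree profile
  fixed, which is the confounder being controlled.
- **Family cooperativity**: statistic = maximum number of module
  miRNAs sharing one family (a miRNA may sit in several families),
  with the ≥2 indicator; null = uniform resampling from the miRNA
  universe.
- **Three-layer network**: the mixed graph on module members from
  miRNA→gene and gene–gene edges; miRNA edges are directed for layer
  assignment (direct vs indirect genes) but undirected for
  connectivity, since the reported object is the largest connected
  subnetwork. Component ties break by size then smallest node label.

## Survival screen

Per (module, cancer in the module's support): the module's genes and
miRNAs are pooled, columns standardized, and samples scored by the
first principal component of the feature covariance (sign fixed so the
largest loading is positive; the split is sign-invariant). Samples at
or below the median score form the low group — ties go low, so group
sizes can differ under heavy ties — and the two groups are compared
with the standard two-group log-rank test (lifelines), p from
chi-square with 1 df. The per-miRNA screen scores samples by each
single miRNA's expression instead. All p-values of one screen are
BH-adjusted as a single family, and pairs with adjusted p < 0.05 form
the module-cancer bipartite graph. Restricting to each module's
support cancers is the default; a flag tests all cancers. Times are in
whatever unit the clinical table uses (days for typical cohorts); the
log-rank statistic is unit-invariant.

## Synthetic data

`paper_default_config()` is the reference protocol: A ∈ R^{300×30×4},
background N(0, 0.2²), three planted 100-gene × 10-miRNA blocks with
entries N(±0.5, 0.2²) — block 1 positive in cancer 1 and negative in
cancer 2, block 2 negative in 1 and positive in 3, block 3 positive in
2 and negative in 3 — and cancer 4 pure noise. Entries are left
unclipped by default so the draws follow the stated normals exactly
(rare tail values can exceed |1|; a clip flag builds valid correlation
tensors). A planted module's cancer set is the set of slices it
appears in regardless of sign, since the rank-1 model absorbs signs
into w. Gene/miRNA shuffling is tracked through the truth and exactly
invertible.

`generate_expression` emulates the matched-cohort route: per planted
module and cancer, a latent standard-normal factor is mixed into the
block's genes and miRNAs with loadings √|ρ| (sign carried on the miRNA
side), giving population gene-miRNA correlation exactly ρ inside the
block; everything else is independent noise. What this does *not*
emulate: heavy-tailed and count-like expression, sample covariates and
batch structure, correlated backgrounds, and missingness — so passing
tests demonstrate correctness of the machinery on the stated model,
not robustness to real-data pathologies.

Recovered modules are scored as (gene, miRNA, cancer) cell sets:
Recovery = mean over true modules of the best Jaccard index against
any prediction (higher better); CE = 1 − (weight of the optimal
one-to-one truth/prediction matching, by shared cells) / |union of all
cells| (lower better), with the matching via the Hungarian algorithm.
These are the standard tri-cluster conventions; under them the tensor
fit at true sparsity attains Recovery 1.0 / CE 0.0 on the default
protocol, while per-slice sparse CCA cannot exceed Recovery ≈ 0.5
structurally (one module per slice, no cancer selection).

## Problem sizes in the test suite

The suite exercises the full 300 × 30 × 4 protocol (20 replicates for
the benchmark, ~2 s total), exhaustive-enumeration oracles on vectors
of length ≤ 10 and graphs of ≤ 12 nodes, and 300-replicate type-I
calibration of each permutation test at n_perm = 200 with rejection
rates required to fall in the binomial 99% interval around α = 0.05.
The calibration fixtures are chosen so each test's statistic is
well-resolved (a circulant graph makes degree bins vacuous for the
degree-aware test, giving an exact self-null; overlap calibration uses
supports large enough that integer ties do not dominate).

## Known limitations

- Block-coordinate ascent finds local optima; the slice-start strategy
  removes the known cancellation failure mode but is not a global
  guarantee. Random restarts are available and seeded.
- Sparsity levels are configuration, not inference: no automatic
  selection of (k_u, k_v, k_w) is provided.
- The deflated residual is not renormalized or clipped; it is flagged
  as not-built-from-data and later fits treat it as a plain tensor.
- Missing expression values are rejected, not imputed; imputation and
  differential-expression pre-filtering are upstream concerns.
- miRNA identifiers are opaque strings; harmonizing mature-form names
  across annotation sources is left to the user.
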