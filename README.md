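# tscca

Tensor sparse canonical correlation analysis for cancer-miRNA-gene
co-expression modules.

## The problem

MicroRNAs regulate gene expression post-transcriptionally, and their
dysregulation is implicated across many cancers. Given matched mRNA and
miRNA expression cohorts for M cancer types, one wants the recurring
*modules* — a small set of genes, a small set of miRNAs, and the subset
of cancers in which they are strongly co-expressed — rather than one
correlation analysis per cancer. This package is for computational
biologists doing that pan-cancer integration: it stacks the per-cancer
gene × miRNA Pearson correlation matrices into a three-way tensor and
factors it into sparse rank-1 components, each one a
cancer-miRNA-gene module.

## The model

Let X_k (n_k × p) and Y_k (n_k × q) be the column-standardized gene and
miRNA expression of cancer k, and A the p × q × M tensor with frontal
slices A_k = X_kᵀY_k / (n_k − 1) (exact sample Pearson correlations).
TSCCA seeks unit vectors u ∈ R^p, v ∈ R^q, w ∈ R^M solving

    max_{u,v,w}  Σ_k w_k · (uᵀ A_k v)
    s.t.  ‖u‖₀ ≤ k_u,  ‖v‖₀ ≤ k_v,  ‖w‖₀ ≤ k_w,  ‖u‖₂ = ‖v‖₂ = ‖w‖₂ = 1.

Each block subproblem has a closed form via the k-sparse projection
Π(z, k) (keep the k largest-|·| entries, zero the rest): the optimal
factor is Π(z, k)/‖Π(z, k)‖₂ for the appropriate score vector z
(z_u = (Σ_k w_k A_k)v, z_v = (Σ_k w_k A_k)ᵀu, z_w = [uᵀA_k v]_k).
Block-coordinate ascent therefore increases the objective monotonically;
the value d at the fixed point is the module's singular value, and the
nonzero entries of u, v, w are the module's genes, miRNAs and cancers.
Further modules come from deflation (A ← A − d·u∘v∘w). The battery
around the solver — modularity permutation tests, hypergeometric and
degree-aware edge enrichment, miRNA-family cooperativity, three-layer
regulatory subnetworks, and a PC1 median-split log-rank survival screen
with BH correction — quantifies whether fitted modules are coherent,
annotated, and prognostic.

## Worked example

`examples/01_fit_simulated_modules.py` generates a 300 × 30 × 4
synthetic tensor with three planted 100-gene × 10-miRNA blocks (mean
correlation ±0.5, sd 0.2, each spanning two cancers with opposite
signs), shuffles it, and fits three modules at the true sparsity:

```
module 1: d = 22.50, supports = (100 genes, 10 miRNAs, 2 cancers), converged in 5 sweeps
module 2: d = 22.33, supports = (100 genes, 10 miRNAs, 2 cancers), converged in 5 sweeps
module 3: d = 22.06, supports = (100 genes, 10 miRNAs, 2 cancers), converged in 5 sweeps
Recovery = 1.000 (1.0 = every planted module matched exactly)
CE       = 0.000 (0.0 = perfect reconstruction)
```

Every planted module is recovered exactly: Recovery (mean best-match
Jaccard between true and fitted modules) is 1.0 and the clustering
error CE is 0.0; the three singular values are nearly equal because the
three planted blocks are equally strong. The other examples walk
through tensor construction from expression
(`02_build_tensor_from_expression.py`), modularity and overlap
statistics (`03_module_statistics.py`), enrichment and network
extraction (`04_enrichment_and_networks.py`), and the survival screen
(`05_survival_screen.py`).

A thin command-line interface wraps the same stages:

```sh
tscca simulate --out sim --seed 7
tscca fit --tensor sim/tensor.h5 --out fit --modules 3 \
      --k-genes 100 --k-mirnas 10 --k-cancers 2
tscca evaluate --truth sim/truth.tsv --modules fit --tensor sim/tensor.h5
```

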