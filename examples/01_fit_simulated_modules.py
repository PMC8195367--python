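"""Fit sparse rank-1 modules to a synthetic correlation tensor.

Generates the default 300-gene × 30-miRNA × 4-cancer tensor with three
planted co-expression blocks, shuffles gene and miRNA order, fits three
modules with the true sparsity (100 genes, 10 miRNAs, 2 cancers), and
scores the reconstruction against the planted truth.
"""

from tscca import (SparsityParams, ce_score, generate_tensor,
                   paper_default_config, recovery_score, shuffle_tensor,
                   tscca_multi)

tensor, truth = generate_tensor(paper_default_config(), seed=0)
tensor, truth = shuffle_tensor(tensor, truth, seed=1)

modules = tscca_multi(tensor, r=3, params=SparsityParams(100, 10, 2))

for i, m in enumerate(modules.modules, start=1):
    print(f"module {i}: d = {m.d:.2f}, supports = "
          f"({len(m.I)} genes, {len(m.J)} miRNAs, {len(m.K)} cancers), "
          f"converged in {m.iterations} sweeps")
print(f"Recovery = {recovery_score(truth, modules.modules):.3f} "
      f"(1.0 = every planted module matched exactly)")
print(f"CE       = {ce_score(truth, modules.modules):.3f} "
      f"(0.0 = perfect reconstruction)")
# The singular value d ranks modules by co-expression strength; with
# three equally strong planted blocks all d are close.
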