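"""Annotation statistics on a module's genes and miRNAs.

Builds a toy annotation bundle (cancer gene set, miRNA families, an
interaction network), then runs the right-tailed hypergeometric
enrichment, the degree-aware edge test, the family cooperativity test,
and extracts the three-layer miRNA -> gene -> gene subnetwork.
"""

import numpy as np

from tscca.enrichment import (degree_aware_edge_test, edge_enrichment,
                              extract_three_layer_network,
                              family_cooperativity, hypergeometric_enrichment)

rng = np.random.default_rng(8)
genes = [f"g{i}" for i in range(200)]
mirnas = [f"m{j}" for j in range(40)]
module_genes = set(genes[:30])
module_mirnas = set(mirnas[:6])

# cancer gene set enriched in the module: 12 of 30 members vs 30 of 200
cancer_genes = set(genes[:12]) | set(genes[150:168])
res = hypergeometric_enrichment(module_genes, cancer_genes, genes)
print(f"cancer genes in module: {res.overlap}/{res.set_size}, "
      f"fold = {res.fold_enrichment:.1f}, hypergeometric p = {res.p_value:.2e}")

# gene-gene network denser inside the module
gg = {frozenset((genes[a], genes[b]))
      for a, b in rng.integers(0, 200, size=(300, 2)) if a != b}
gg |= {frozenset((genes[a], genes[b]))
       for a, b in rng.integers(0, 30, size=(60, 2)) if a != b}
res = edge_enrichment(module_genes, gg, genes)
print(f"gene interactions in module: {res.overlap}, "
      f"fold = {res.fold_enrichment:.1f}, p = {res.p_value:.2e}")
aware = degree_aware_edge_test(module_genes, gg, genes, n_perm=1000, seed=1)
print(f"degree-aware permutation p = {aware.p_value:.4g} "
      f"(discounts hub-driven enrichment)")

families = {"fam-17": set(mirnas[:5]), "fam-8": set(mirnas[20:27])}
fam = family_cooperativity(module_mirnas, families, mirnas, n_perm=1000, seed=2)
print(f"max miRNAs sharing a family = {fam.max_shared_family}, "
      f"p = {fam.p_value:.4g} -> cooperative = {fam.has_cooperative_pair}")

mg = {(m, g) for m in module_mirnas for g in list(module_genes)[:8]
      if rng.random() < 0.4}
net = extract_three_layer_network(module_genes, module_mirnas, mg, gg)
c = net.counts
print(f"three-layer subnetwork: {c['mirnas']} miRNAs directly regulate "
      f"{c['direct_genes']} genes, which connect {c['indirect_genes']} more "
      f"({c['edges']} edges in the largest component)")
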