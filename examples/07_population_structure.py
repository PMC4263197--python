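"""Relatedness filtering, LD pruning and PCA on merged genotypes.

Estimates KING-robust kinship (duplicates ≈ 0.5, parent-offspring
≈ 0.25), keeps one member per relative cluster at the 0.125
second-degree threshold, LD-prunes to common near-independent markers
and computes principal components with a scree summary.
"""

import numpy as np

from imputemerge import SimulationConfig, simulate_reference
from imputemerge.popstruct import king_kinship, ld_prune, pca, select_unrelated

config = SimulationConfig(seed=1, n_ref_haplotypes=400, n_subpops=2,
                          divergence=0.05, n_founders=80)
panel = simulate_reference(config)
genotypes = panel.dosages().astype(np.int8)  # 200 individuals, 2 subpops
ids = [f"ind{i}" for i in range(genotypes.shape[1])]
# append an exact duplicate of individual 0 to show the kinship tiers
genotypes = np.hstack([genotypes, genotypes[:, :1]])
ids.append("ind0_dup")

estimates = king_kinship(genotypes, ids)
dup = next(e for e in estimates if {e.sample_i, e.sample_j} == {"ind0", "ind0_dup"})
print(f"kinship of the duplicate pair: {dup.phi:.3f} (expected ~0.5)")
related = [e for e in estimates if e.phi > 0.125]
unrelated_ids = select_unrelated(estimates, ids, threshold=0.125)
print(f"{len(related)} pairs above the 0.125 threshold; "
      f"{len(unrelated_ids)} of {len(ids)} samples kept")

keep_cols = [ids.index(s) for s in unrelated_ids]
g = genotypes[:, keep_cols]
pruned = ld_prune(g, window=100, r2_threshold=0.1, maf_floor=0.10)
print(f"LD pruning: {len(pruned)} of {g.shape[0]} markers retained "
      "(MAF > 10%, pairwise r2 < 0.1 in 100-marker windows)")

components, explained = pca(g[pruned], n_components=10)
print("variance explained by the first 5 PCs:",
      " ".join(f"{v:.3f}" for v in explained[:5]))
pc1 = components[:, 0]
print(f"PC1 range: [{pc1.min():.2f}, {pc1.max():.2f}] — the two "
      "subpopulations separate along PC1; later PCs carry little variance.")
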