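"""Sample clustering with multiscale bootstrap support and classical MDS.

Clusters the 15 embryo libraries by Pearson-correlation distance (complete
linkage), attaches bootstrap-probability (BP) and approximately-unbiased
(AU) support to every cluster, and embeds the samples in two dimensions.
"""

from coexnet import (
    SimConfig, classical_mds, filter_abundance, filter_variance,
    multiscale_bootstrap, sample_cor_dist, simulate_counts, tmm_normalize,
)
from coexnet.io import dendrogram_to_newick

cm, _ = simulate_counts(SimConfig(seed=5))
expr = tmm_normalize(filter_abundance(cm))
values, _ = filter_variance(expr.values)

support = multiscale_bootstrap(values, n_boot=1000, seed=5)
print(support.table[["leaves", "bp", "au"]].sort_values("au", ascending=False)
      .head(8).to_string(index=False))

coords, eigvals = classical_mds(sample_cor_dist(values), k=2)
print("\nMDS coordinates (dimension 1 orders the samples by stage):")
print(coords.round(3).to_string())

print("\nNewick with AU/BP tags:")
print(dendrogram_to_newick(support.dendrogram, support.table)[:120] + "...")

# AU near 1 marks clusters that persist across gene resamples of varying
# size; early-stage and late-stage libraries separate along MDS dimension 1,
# mirroring the major mid-development expression shift.
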