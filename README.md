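# coexnet

Stage-resolved weighted gene co-expression network analysis for short
developmental RNA-seq time courses.

`coexnet` is built for studies of the kind where a handful of bulk RNA-seq
libraries — one individual per library — span the stages of embryonic
development, and the question is which groups of genes rise and fall
together, how those groups track developmental time, and whether any of
them are driven by a covariate nobody recorded (such as the sex of each
embryo). It packages the full analysis as a tested, reusable library:

- **Preprocessing** — CPM-based abundance filtering, a variance filter,
  trimmed-mean-of-M-values (TMM) normalization, log2 expression, RPKM
  binning, stage-core gene sets, and assembly-completeness arithmetic.
- **Network construction** — biweight midcorrelation (bicor) with capped
  outlier influence (`maxPOutliers`), soft-threshold selection by the
  scale-free topology criterion, signed-hybrid adjacency
  `a_ij = cor_ij^β · 1(cor_ij > 0)`, and the topological overlap measure
  `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`.
- **Module detection** — average-linkage clustering of `1 − TOM`, a
  deterministic adaptive tree cut, module eigengenes (first principal
  component of the standardized member expression), eigengene-correlation
  merging, module–trait correlation with BH control, and kME-based hub
  genes.
- **Hidden-covariate scan** — exhaustive enumeration of all
  `2^(n−1) − 1` sample bipartitions (16,383 for 15 samples), each tested
  against each module eigengene with Bonferroni control.
- **Sample structure** — complete-linkage clustering on correlation
  distance with multiscale bootstrap support (BP and approximately
  unbiased AU p-values) and classical MDS.
- **Enrichment** — one-sided hypergeometric over-representation with BH
  adjustment, a Wallenius noncentral variant correcting transcript-length
  bias, and rollup of significant terms to slim categories.
- **Synthetic data** — a negative-binomial count simulator that plants
  co-expression modules with early-high / mid-switch / late-high
  trajectories and an optional hidden binary covariate, so every stage of
  the pipeline can be validated against known truth.

## Worked example

```python
from coexnet import PipelineConfig, run_all

summary = run_all(PipelineConfig(seed=1, boot_b=300), "scratch/example_run")
```

On the default synthetic study (2,300 genes, 15 samples over 9 days, three
planted 100-gene modules) this prints a summary equivalent to:

```
genes simulated:        2300
genes after filters:    295
soft power used:        9 (sample_size_default)
modules (pre/post merge): 3/3
recovery ARI vs truth:  0.9798
day/clade-significant:  2 modules
hub genes (kME > 0.9):  288
```

The adjusted Rand index of 0.98 means the detected-and-merged modules
reproduce the planted gene-to-module assignment almost exactly; two of the
three modules correlate with developmental day at FDR < 0.05 (the
mid-development switch module tracks day only weakly, by construction);
and 288 of the 295 module genes exceed the kME > 0.9, p < 1e-6 hub
definition. The scripts under `examples/` walk through each capability —
end-to-end recovery, step-by-step network construction, the hidden
covariate scan, bootstrap-supported sample clustering, and enrichment —
and print what each number means.

A thin CLI mirrors the library:

```bash
coexnet simulate --seed 1 --out run/
coexnet run-all --seed 1 --out run/
coexnet scan-partitions --eigengenes run/eigengenes.tsv --out scan.tsv
```

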