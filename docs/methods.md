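# Methods

This note documents the models, algorithms and numerical choices behind
`coexnet`, in the spirit of a package vignette: what each stage computes,
what its tunable parameters mean, and what the synthetic validation does
and does not demonstrate.

## Study design the package targets

The intended input is a genes × samples matrix of RNA-seq read counts from
a short developmental time course: on the order of 15 libraries, one
individual per library, spanning ~9 consecutive stages (days), with
duplicate individuals on some days. Sample metadata carries the day, a
replicate label, and optionally a coarse "clade" grouping of stages.
Gene lengths (bp) are inputs, never estimated.

## Preprocessing

**Abundance filter.** A gene is kept when its CPM in at least one library
reaches the CPM equivalent of `min_count` (default 5) reads in the
median-depth library. This library-size-aware reading reconciles a
count-based threshold with CPM units: in small studies with unequal
depths, a fixed raw-count rule favours deep libraries. A strict raw-count
mode (`mode="raw"`) is provided. The cutoff is inclusive.

**Variance filter.** Genes whose variance falls below
`factor × overall` (default factor 2) are removed. The "overall"
statistic is configurable: the mean of gene-wise variances (default),
their median, or the pooled within-gene variance (identical to the mean
when all genes share the same residual degrees of freedom). The mean-based
default is deliberately aggressive — it retains only the high-variance
tail, which is the set worth modelling in a co-expression network — and on
synthetic data it removes essentially all flat background genes. Analyses
that need the background retained (e.g. null behaviour of the tree cut)
should lower `factor` or switch to the median statistic.

**TMM normalization.** The reference library is the one whose
upper-quartile CPM is closest to the mean upper-quartile. For each library
against the reference, gene-wise log2 ratios `M` and average log2
abundances `A` are computed over genes expressed in both; both tails of
`M` (30%) and of `A` (5%) are trimmed by rank; the normalization factor is
2 to the precision-weighted mean of the retained `M`, with inverse
delta-method binomial variances as weights; factors are rescaled to
geometric mean 1. This is the standard TMM recipe, and the implementation
reproduces edgeR's `calcNormFactors` to ≤ 1e-5 on a frozen composition-
biased toy (see `tests/test_preprocess.py`). Expression values are
`log2(CPM on effective library sizes + 0.5)`; the 0.5 offset avoids
−∞ at zero counts.

**Expression summaries.** RPKM uses `count × 10⁹ / (library × length)`.
Expression categories follow left-open, right-closed bins: not expressed
(0), low (>0–5], moderate (>5–50], high (>50); finer schemes are
configurable. "Core" genes are those detected (count ≥ 1 by default) in
at least one library of *every* stage. `completeness_summary` turns
benchmark gene-set counts (complete / partial / fragmented / missing)
into recovered and complete percentages rounded to two decimals.

## Network construction

**Biweight midcorrelation.** Per gene, deviations from the median are
scaled by nine times the median absolute deviation, `u = (x − m)/(9·MAD)`;
Tukey biweights `(1 − u²)²·1(|u| < 1)` downweight outlying samples.
Before weighting, each side of `u` is rescaled so that at most
`maxPOutliers` (default 0.1) of the samples per side fall outside
|u| ≥ 1 — the side quantile maps to ±1 only when it would otherwise
exceed it. Genes with zero MAD fall back to Pearson and are flagged.
The statistic is separable per gene, so the full matrix is a normalized
cross-product of per-gene weighted deviation vectors. Caveat worth knowing:
with few samples and step-like profiles (a long flat baseline plus a short
active phase), the MAD comes from the baseline and the active samples are
downweighted as "outliers", attenuating exactly the informative part of
the profile. This is inherent to the estimator, not an implementation
artifact; the synthetic trajectories are smooth partly so that validation
is not dominated by this effect.

**Soft threshold.** For each candidate power β (default 1–30), the
signed-hybrid connectivity `k_i = Σ_j a_ij` (diagonal excluded) is binned
into 10 equal-width bins and `log10(frequency)` is regressed on
`log10(mean k)`. The signed fit index is `−sign(slope)·R²`; the chosen β
is the smallest reaching the target (default 0.85, with the knowledge
that well-behaved bulk data typically reach ~0.85–0.9), else the argmax;
near-constant connectivity flags the fit as degenerate and an
all-degenerate scan returns no choice. The pipeline adds one policy on
top: when no candidate reaches the target — routine for small planted
simulations, whose degree distribution is a few spikes rather than a
power law — it uses the field-standard sample-size default
(9 for signed-hybrid networks below 20 samples) instead of the argmax of
a failed fit, and records which source decided the power. Scale-free fit
failure is information about the data, not a license for an extreme β.

**Adjacency and TOM.** Signed-hybrid adjacency zeroes negative
correlations and raises positive ones to β. The topological overlap
`TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)` (unit
diagonal) counts shared neighbours; `1 − TOM` is the clustering
dissimilarity. Matrices are dense; a configurable cap (default 5,000
genes) guards against accidental quadratic blow-ups.

## Module detection

**Adaptive tree cut.** Modules are branches of the average-linkage
dendrogram of `1 − TOM`, found by a deterministic height-profile
decomposition:

1. a static cut at 0.99 of the maximum merge height yields candidate
   branches;
2. a branch splits into its two children when both hold at least
   `min_module_size` leaves (default 50) and both hang below the join by
   at least `gap_frac × (join − mean internal merge height)`, with
   `gap_frac = 0.3 − 0.05·deep_split` (deep_split 0–4, default 2);
3. a terminal branch is accepted as a module when it satisfies the same
   branch-relative gap against the height at which it joins the rest of
   the tree; otherwise, small late-attaching side branches ("stragglers")
   are peeled off the top and the remaining core retried against the
   original join.

The mean internal merge height makes the gap requirement scale with each
branch's own profile: tight modules under a high join pass easily, while
structureless aggregates — whose merge heights pile up just below the
join — fail. On simulated no-structure inputs the assigned fraction is
~0. The procedure is fully deterministic (module ids by decreasing size,
ties by smallest leaf index). The alternative hybrid variant with
medoid-style reassignment of leftover genes is deliberately out of scope.

**Eigengenes, merging, traits, hubs.** A module eigengene is the first
right singular vector (across samples) of the member expression after
per-gene standardization, oriented so its mean correlation with members
is non-negative; the fraction of variance explained is reported, and
constant genes are excluded with a warning. Merging groups modules by
transitive closure of eigengene dissimilarity `1 − cor < threshold`
(default 0.1, i.e. correlation above 0.9 merges), recomputes eigengenes
and repeats to a fixed point; the history of every round is kept.
Module–trait association is the Pearson correlation of eigengenes with
numeric traits, with exact Student-t p-values
(`t = r√((n−2)/(1−r²))`, n−2 df, two-sided) and BH adjustment per trait
family by default (the global family is available; which family a given
study wants is a judgement call, so it is a parameter). Module
membership kME is each gene's correlation with each eigengene; hub genes
are members with kME > 0.9 and correlation p < 1e-6. Note the two hub
rules interact with sample size: at n = 15, kME = 0.9 has p ≈ 4.9e-6,
so a gene exactly at the kME cutoff is *not* a hub — the p-rule binds
until kME ≈ 0.93.

## Hidden-covariate (bipartition) scan

All `2^(n−1) − 1` unordered two-group splits of the samples are
enumerated in a canonical form (sample 1 pinned to group 0, so
complements never recur) — 16,383 splits for 15 samples. Each module
eigengene is correlated with each 0/1 indicator; p-values use the same
exact t transform, valid for a fixed indicator under the Gaussian null.
The Bonferroni multiplier defaults to partitions × modules (the whole
scan is one family); a partitions-only multiplier is available and the
choice is recorded in the result. Under a 10,000-replicate independent-
Gaussian null with 34 modules and 15 samples, the measured family-wise
error rate at α = 0.01 is ≈ 0.01 (Bonferroni is nearly exact here
because the per-test level is tiny). The enumeration streams indicator
blocks, so memory stays modest, and the null simulation is evaluated in
vectorized replicate chunks.

## Sample structure

Sample dissimilarity is `1 − Pearson` over genes; clustering is complete
linkage. Multiscale bootstrap support resamples *genes* (the features)
with replacement at 10 scales, 0.5–1.4 times the gene count (the
standard scale grid; only the iteration count is usually reported in
papers). For each observed cluster (exact leaf-set identity; near-misses
do not count) the containment frequency `BP_r` per scale is transformed
as `z_r = Φ⁻¹(1 − BP_r)` after clipping into `[1/(B+1), B/(B+1)]` and
fitted by weighted least squares to `z_r = v√r + c/√r` with binomial
delta-method weights; `AU = 1 − Φ(v − c)`, and BP is reported at scale 1.
Clusters present (absent) in every resample at every scale short-circuit
to AU = 1 (0) with a flag, since the two-parameter fit is undefined on a
constant clipped profile. Degenerate resamples that produce a constant
sample are counted as not containing any cluster. Classical MDS
double-centers `−½d²` and keeps the top-k eigenvectors scaled by root
eigenvalues, dropping non-positive eigenvalues (reported for diagnosis
of non-Euclidean input).

## Enrichment

Over-representation of a gene set against annotation terms uses the
one-sided hypergeometric upper tail per term, restricted to terms present
in the supplied universe, with BH adjustment across terms. The
length-bias-aware variant fits a monotone selection-probability-vs-length
function by pool-adjacent-violators isotonic regression over ~30
equal-count length bins (deterministic, in place of a spline fit), and
tests each term with the Wallenius noncentral hypergeometric distribution
using odds = mean weight inside the term / mean weight outside. With
constant weights the odds are 1 and the test reduces to the central
hypergeometric within 1e-6. Annotations are taken as given (no ontology-
graph propagation); slim rollup counts significant terms per category,
sending unmapped terms to "other".

## Synthetic data generator

The generator emulates the target study design: 15 libraries over days
1–9 (days 1–6 duplicated), library sizes uniform in 0.8–1.2 million reads
(per-library depth is rarely published for such studies; this is a
realistic desk-scale choice), gene lengths uniform in 300–5,000 bp, and
negative-binomial counts with variance `μ + αμ²` (default α = 0.08, a
typical bulk biological dispersion). Module genes follow
`log2 mean = baseline + loading × trajectory(sample)` with baselines
uniform in log2 units (3–9), loadings Normal(2.0, 0.35); expected counts
are rescaled per sample so totals match the drawn library size.
Trajectories are built from logistic ramps of day and standardized:

- *early_high* — high on days 1–4, declining after mid-development, with
  a mild late recovery;
- *mid_switch* — its antagonist: low early, peaking after
  mid-development, dipping again on the final days;
- *late_high* — rising from around day 5 to a peak at days 8–9.

The ramps are smooth (scales of roughly a fifth of the day span) so that
each trajectory varies across most samples. This mirrors gradual
developmental regulation and keeps the planted structure detectable by a
median/MAD-based correlation; perfectly step-like trajectories would be
both less realistic and pathological for the biweight (see above). The
pairwise trajectory correlations on the default design are −0.70
(early/mid), −0.81 (early/late) and +0.15 (mid/late). A
*covariate_linked* module follows a hidden balanced binary labelling of
samples instead of the day axis; the labelling is withheld from the trait
table by default. All randomness flows from one seed through named
`SeedSequence` children (lengths, baselines, loadings, covariate,
libsizes, counts), so identical seeds give bit-identical output.

**What passing synthetic tests shows, and what it does not.** The
simulator plants clean block structure with homogeneous NB noise; real
data add unmodelled batch effects, overlapping modules, isoform-level
artifacts and expression-dependent dispersion. Recovery of planted
modules (ARI ≈ 0.97–0.99 at the default signal-to-noise across seeds)
validates the plumbing and the contracts between stages — filters,
robust correlation, TOM, tree cut, merging — not the biological adequacy
of any particular threshold on real data. Likewise the bipartition-scan
FWER simulation certifies error control under an idealized Gaussian
null, not under correlated eigengenes from a shared network fit.

## Problem sizes and determinism

Default validation sizes are desk-scale: 2,300 simulated genes (networks
of ~300 genes after the aggressive variance filter), 15 samples, 1,000
bootstrap iterations in examples and the acceptance script (10,000 remain
the method default), and 10,000 replicates for the null simulations.
These sizes keep the whole suite and the acceptance script in the
low minutes on one CPU while leaving every statistic's Monte-Carlo error
well below its acceptance margin; estimates against a probabilistic
bound are compared with a two-standard-error binomial allowance. Every
stochastic component takes an explicit seed, and the pipeline summary is
byte-identical across reruns of the same configuration.
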