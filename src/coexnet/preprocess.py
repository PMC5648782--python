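"""Count filtering, TMM normalization and stage-level expression summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class CountMatrix:
    """Raw genes x samples counts with gene lengths and sample metadata.

    ``sample_meta`` rows align with count columns and carry at least a
    ``day`` column (integer stage label) and an ``individual`` replicate
    label; a ``clade`` column may be added by the caller.
    """

    counts: pd.DataFrame
    gene_length_bp: pd.Series
    sample_meta: pd.DataFrame
    filter_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.index.equals(self.gene_length_bp.index):
            self.gene_length_bp = self.gene_length_bp.reindex(self.counts.index)
        if self.gene_length_bp.notna().any() and (self.gene_length_bp.dropna() <= 0).any():
            raise ValueError("gene lengths must be positive")
        if len(self.sample_meta) != self.counts.shape[1]:
            raise ValueError("sample_meta rows must match count columns")

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, genes: pd.Index, step: str, reason: str) -> "CountMatrix":
        removed = self.counts.index.difference(genes)
        log = self.filter_log + [
            {"step": step, "rule": reason, "removed": int(len(removed)),
             "kept": int(len(genes))}
        ]
        return CountMatrix(
            counts=self.counts.loc[genes],
            gene_length_bp=self.gene_length_bp.loc[genes],
            sample_meta=self.sample_meta,
            filter_log=log,
        )


@dataclass
class ExprMatrix:
    """log2 TMM-normalized expression with the normalization factors used."""

    values: pd.DataFrame  # genes x samples, log2 scale
    tmm_factors: pd.Series
    filter_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        gm = np.exp(np.log(self.tmm_factors.values).mean())
        if abs(gm - 1.0) > 1e-8:
            raise ValueError("TMM factors must have geometric mean 1")


def cpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts per million: ``count * 1e6 / library size``."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    totals = df.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total library: {', '.join(map(str, zero.index))}")
    return df * 1e6 / totals


def rpkm(counts: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase per million: ``count * 1e9 / (library size * length)``."""
    missing = counts.gene_length_bp[counts.gene_length_bp.isna()]
    if len(missing):
        raise ValueError(f"missing gene length for: {', '.join(map(str, missing.index[:5]))}")
    totals = counts.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total library: {', '.join(map(str, zero.index))}")
    return counts.counts * 1e9 / totals / counts.gene_length_bp.values[:, None]


def filter_abundance(counts: CountMatrix, min_count: int = 5, mode: str = "cpm") -> CountMatrix:
    """Keep genes detected above a minimum abundance in at least one library.

    ``mode='cpm'`` (default) keeps a gene when its CPM in some library reaches
    the CPM equivalent of ``min_count`` reads in the median-depth library, so
    the cutoff accounts for library-size differences; ``mode='raw'`` applies
    the plain raw-count rule (>= min_count reads in >= 1 library).  The cutoff
    is inclusive.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if mode == "raw":
        keep = (counts.counts >= min_count).any(axis=1)
        rule = f"raw count >= {min_count} in >= 1 library"
    elif mode == "cpm":
        cutoff = min_count * 1e6 / float(np.median(counts.lib_sizes.values))
        keep = (cpm(counts) >= cutoff).any(axis=1)
        rule = f"CPM >= {cutoff:.6g} (= {min_count} counts at median depth) in >= 1 library"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return counts.subset_genes(counts.counts.index[keep], "abundance", rule)


def filter_variance(
    expr: pd.DataFrame, factor: float = 2.0, stat: str = "mean"
) -> tuple[pd.DataFrame, pd.Index]:
    """Drop genes whose variance falls below ``factor`` x an overall statistic.

    The overall statistic summarizes gene-wise variances: their ``mean``
    (default), ``median``, or the ``pooled`` within-gene variance (total
    centered sum of squares over total degrees of freedom).  Returns the
    filtered matrix and the removed gene index.
    """
    if factor < 0:
        raise ValueError("factor must be non-negative")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    gene_var = expr.var(axis=1, ddof=1)
    if stat == "mean":
        overall = gene_var.mean()
    elif stat == "median":
        overall = gene_var.median()
    elif stat == "pooled":
        centered = expr.sub(expr.mean(axis=1), axis=0)
        overall = (centered.values**2).sum() / (expr.shape[0] * (expr.shape[1] - 1))
    else:
        raise ValueError(f"unknown stat {stat!r}")
    keep = gene_var >= factor * overall
    return expr.loc[keep], expr.index[~keep]


def tmm_normalize(
    counts: CountMatrix,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
    ref_sample: str | None = None,
) -> ExprMatrix:
    """Trimmed mean of M-values normalization, log2 expression output.

    The reference library is the one whose upper-quartile CPM is closest to
    the mean upper-quartile.  For each library, gene-wise log2 ratios M and
    average abundances A against the reference (over genes expressed in both)
    are doubly trimmed (``trim_M`` of each M tail, ``trim_A`` of each A tail);
    the factor is 2 to the precision-weighted mean of the retained M values,
    with weights from the binomial delta-method variance.  Factors are
    rescaled to geometric mean 1 and expression is
    ``log2(count * 1e6 / (lib size * factor) + 0.5)``.
    """
    if counts.counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    x = counts.counts.values.astype(float)
    lib = x.sum(axis=0)
    if (lib == 0).any():
        bad = counts.counts.columns[lib == 0]
        raise ValueError(f"zero-total library: {', '.join(map(str, bad))}")

    cols = list(counts.counts.columns)
    if ref_sample is None:
        uq = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(len(cols))])
        ref = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref = cols.index(ref_sample)

    factors = np.ones(len(cols))
    for j in range(len(cols)):
        if j == ref:
            continue
        factors[j] = _tmm_pair(x[:, j], x[:, ref], lib[j], lib[ref], trim_M, trim_A)
    factors = factors / np.exp(np.mean(np.log(factors)))

    eff_lib = lib * factors
    values = np.log2(x * 1e6 / eff_lib[None, :] + 0.5)
    return ExprMatrix(
        values=pd.DataFrame(values, index=counts.counts.index, columns=counts.counts.columns),
        tmm_factors=pd.Series(factors, index=counts.counts.columns, name="tmm_factor"),
        filter_log=list(counts.filter_log),
    )


def _tmm_pair(obs, ref, n_obs, n_ref, trim_M, trim_A) -> float:
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise ValueError("library shares no expressed genes with the reference")
    obs, ref = obs[both], ref[both]
    po, pr = obs / n_obs, ref / n_ref
    M = np.log2(po / pr)
    A = 0.5 * np.log2(po * pr)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(M) & np.isfinite(A)
    M, A, w = M[fin], A[fin], w[fin]
    n = len(M)
    if n == 0:
        raise ValueError("no usable genes for TMM after filtering")
    # rank-based double trim, keeping ranks inside both trimmed windows
    loM = np.floor(n * trim_M) + 1
    hiM = n + 1 - loM
    loA = np.floor(n * trim_A) + 1
    hiA = n + 1 - loA
    rM = rankdata(M)
    rA = rankdata(A)
    keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    if not keep.any():
        return 1.0
    f = 2 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    if not np.isfinite(f) or abs(np.log2(f)) < 1e-10:
        return 1.0
    return f


_THREE_BINS = ((0.0, 5.0, "low"), (5.0, 50.0, "moderate"), (50.0, np.inf, "high"))


def bin_expression(
    rpkm_values: pd.DataFrame,
    edges: tuple[float, ...] | None = None,
    labels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Bin RPKM values into expression categories.

    Default categories follow left-open, right-closed intervals:
    not_expressed (0), low (>0-5], moderate (>5-50], high (>50).  A finer
    scheme is available by passing increasing ``edges`` (interior bin
    boundaries above zero) and matching ``labels`` (len(edges) + 1 of them).
    """
    if (rpkm_values.values < 0).any():
        raise ValueError("RPKM values must be non-negative")
    if edges is None:
        edges = (5.0, 50.0)
        labels = ("low", "moderate", "high")
    edges = tuple(float(e) for e in edges)
    if any(b <= a for a, b in zip(edges, edges[1:])) or edges[0] <= 0:
        raise ValueError("edges must be strictly increasing and positive")
    if labels is None or len(labels) != len(edges) + 1:
        raise ValueError("need len(edges) + 1 labels")
    full = (0.0,) + edges + (np.inf,)
    cats = ("not_expressed",) + tuple(labels)
    out = np.empty(rpkm_values.shape, dtype=object)
    v = rpkm_values.values
    out[v == 0] = "not_expressed"
    for lo, hi, lab in zip(full[:-1], full[1:], cats[1:]):
        out[(v > lo) & (v <= hi)] = lab
    return pd.DataFrame(out, index=rpkm_values.index, columns=rpkm_values.columns)


def core_genes(counts: CountMatrix, min_detect: int = 1) -> pd.Index:
    """Genes detected (count >= min_detect) in >= 1 library of every stage."""
    days = counts.sample_meta["day"]
    keep = np.ones(counts.counts.shape[0], dtype=bool)
    for day in sorted(days.unique()):
        libs = counts.sample_meta.index[days == day]
        keep &= (counts.counts[libs] >= min_detect).any(axis=1).values
    return counts.counts.index[keep]


def completeness_summary(
    complete: int, partial: int, fragmented: int, missing: int
) -> dict[str, float]:
    """Assembly-completeness percentages from benchmark gene-set counts.

    ``recovered_pct`` counts complete plus partially/fragment-recovered genes
    over the whole assessed set; ``complete_pct`` counts only complete ones.
    Both are rounded to two decimals, matching the convention of benchmark
    reports (e.g. 245 of 248 conserved genes -> 98.79).
    """
    for v in (complete, partial, fragmented, missing):
        if v < 0:
            raise ValueError("counts must be non-negative")
    total = complete + partial + fragmented + missing
    if total == 0:
        raise ValueError("at least one count must be positive")
    return {
        "total": float(total),
        "recovered_pct": round(100.0 * (complete + partial + fragmented) / total, 2),
        "complete_pct": round(100.0 * complete / total, 2),
    }
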