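"""Sample-level structure: bootstrap-supported clustering and classical MDS.

Samples are compared by Pearson correlation of their expression profiles and
clustered with complete linkage.  Cluster support comes from multiscale
bootstrap resampling of genes: resamples of several sizes around the
original gene count give a bootstrap probability per cluster and scale, and
a two-parameter fit across scales yields the approximately unbiased (AU)
p-value that corrects the plain bootstrap probability (BP) for its
well-known bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm

from .modules import Dendrogram, hclust_complete

DEFAULT_SCALES = tuple(np.round(np.linspace(0.5, 1.4, 10), 10))


def sample_cor_dist(expr: pd.DataFrame) -> pd.DataFrame:
    """Sample dissimilarity ``1 - Pearson correlation`` over genes."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = expr.values.astype(float)
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = expr.columns[sd == 0]
        raise ValueError(f"constant sample(s): {', '.join(map(str, bad))}")
    d = 1.0 - np.corrcoef(x, rowvar=False)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=expr.columns, columns=expr.columns)


def _cluster_sets(z: np.ndarray, n: int) -> list[frozenset]:
    """Leaf sets of all internal nodes of a linkage matrix."""
    sets: list[frozenset] = [frozenset([i]) for i in range(n)]
    for a, b, *_ in z:
        sets.append(sets[int(a)] | sets[int(b)])
    return sets[n:]


@dataclass
class DendrogramSupport:
    """Per-cluster bootstrap support of a sample dendrogram."""

    dendrogram: Dendrogram
    table: pd.DataFrame  # per cluster: leaves, bp, au, v, c, wls_residual, flag
    scales: tuple[float, ...]
    n_boot: int
    seed: int
    bp_matrix: pd.DataFrame  # clusters x scales, raw bootstrap probabilities


def multiscale_bootstrap(
    expr: pd.DataFrame,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    n_boot: int = 10000,
    seed: int = 0,
    linkage_method: str = "complete",
) -> DendrogramSupport:
    """BP/AU support for sample clusters via multiscale gene resampling.

    For each scale r, ``n_boot`` resamples of ``round(r * n_genes)`` genes
    (with replacement) are drawn, samples are re-clustered, and the fraction
    of resample trees containing each observed cluster is its BP at that
    scale.  BP values (clipped into [1/(B+1), B/(B+1)]) are mapped through
    ``z_r = Phi^-1(1 - BP_r)`` and fit by weighted least squares to
    ``z_r = v * sqrt(r) + c / sqrt(r)`` with binomial-variance weights;
    ``AU = 1 - Phi(v - c)``.  A cluster present (absent) in every resample at
    every scale short-circuits to AU = BP = 1 (0) with a flag.
    """
    import warnings

    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if expr.shape[0] < 10:
        raise ValueError("need at least 10 genes")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives very unstable BP/AU estimates")

    x = expr.values.astype(float)
    g, n = x.shape
    d0 = sample_cor_dist(expr)
    dend = (hclust_complete if linkage_method == "complete" else _hclust_avg)(d0)
    obs_sets = _cluster_sets(dend.linkage, n)
    # root is trivially present in every tree; keep it (support 1) for parity
    set_index = {s: i for i, s in enumerate(obs_sets)}

    rng = np.random.default_rng(seed)
    bp = np.zeros((len(obs_sets), len(scales)))
    for si, r in enumerate(scales):
        size = max(3, int(round(r * g)))
        count = np.zeros(len(obs_sets))
        for _ in range(n_boot):
            idx = rng.integers(0, g, size=size)
            xb = x[idx]
            sd = xb.std(axis=0)
            if (sd == 0).any():
                continue  # degenerate resample: counts as not containing any cluster
            db = 1.0 - np.corrcoef(xb, rowvar=False)
            np.fill_diagonal(db, 0.0)
            db = 0.5 * (db + db.T)
            zb = linkage(squareform(db, checks=False), method=linkage_method)
            for s in _cluster_sets(zb, n):
                i = set_index.get(s)
                if i is not None:
                    count[i] += 1
        bp[:, si] = count / n_boot

    scales_arr = np.asarray(scales, dtype=float)
    rows = []
    for ci, s in enumerate(obs_sets):
        rows.append(_fit_au(bp[ci], scales_arr, n_boot) | {
            "leaves": ",".join(sorted(str(expr.columns[i]) for i in s)),
        })
    table = pd.DataFrame(rows)
    table["bp"] = bp[:, int(np.argmin(np.abs(scales_arr - 1.0)))]
    table = table[["leaves", "bp", "au", "v", "c", "wls_residual", "flag"]]
    bp_df = pd.DataFrame(
        bp, index=pd.RangeIndex(len(obs_sets), name="cluster"), columns=list(scales)
    )
    return DendrogramSupport(
        dendrogram=dend, table=table, scales=tuple(scales), n_boot=n_boot,
        seed=seed, bp_matrix=bp_df,
    )


def _hclust_avg(d):
    from .modules import hclust_average

    return hclust_average(d)


def _fit_au(bp_r: np.ndarray, scales: np.ndarray, n_boot: int) -> dict:
    if np.all(bp_r >= 1.0):
        return {"au": 1.0, "v": np.nan, "c": np.nan, "wls_residual": 0.0,
                "flag": "always_present"}
    if np.all(bp_r <= 0.0):
        return {"au": 0.0, "v": np.nan, "c": np.nan, "wls_residual": 0.0,
                "flag": "never_observed"}
    lo, hi = 1.0 / (n_boot + 1), n_boot / (n_boot + 1.0)
    bp_c = np.clip(bp_r, lo, hi)
    z = norm.ppf(1.0 - bp_c)
    w = n_boot * norm.pdf(z) ** 2 / (bp_c * (1.0 - bp_c))
    X = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
    WX = X * w[:, None]
    beta, *_ = np.linalg.lstsq(X.T @ WX, X.T @ (w * z), rcond=None)
    v, c = beta
    resid = float(np.sum(w * (z - X @ beta) ** 2))
    au = float(1.0 - norm.cdf(v - c))
    return {"au": au, "v": float(v), "c": float(c), "wls_residual": resid,
            "flag": ""}


def classical_mds(dist: pd.DataFrame, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical (Torgerson) multidimensional scaling of a dissimilarity.

    Double-centers ``-0.5 * d**2``, takes the top-k eigenvectors scaled by
    the square roots of their eigenvalues, and drops dimensions with
    non-positive eigenvalues.  Returns (coordinates, all eigenvalues in
    decreasing order); negative eigenvalues diagnose non-Euclidean input.
    """
    n = dist.shape[0]
    if k > n - 1:
        raise ValueError("k must be at most n - 1")
    d = dist.values.astype(float)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = [i for i in range(k) if vals[i] > 1e-12]
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    return (
        pd.DataFrame(
            coords, index=dist.index,
            columns=[f"dim{i + 1}" for i in range(len(keep))],
        ),
        vals,
    )
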