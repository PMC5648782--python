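"""Signed-hybrid weighted co-expression network construction.

The pipeline here follows the step-by-step recipe used in weighted gene
co-expression network analysis: a robust gene-gene correlation (biweight
midcorrelation with capped outlier influence), a soft-thresholding power
chosen by the scale-free topology criterion, a signed-hybrid adjacency
(negative correlations zeroed), and the topological overlap measure whose
complement is the clustering dissimilarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_DENSE_GENES = 5000


@dataclass
class CorrelationMatrix:
    values: pd.DataFrame  # genes x genes, in [-1, 1], unit diagonal
    method: str = "bicor"
    max_p_outliers: float = 0.1
    pearson_fallback: tuple = ()  # genes with zero MAD, computed as Pearson


@dataclass
class PowerFitResult:
    """Scale-free fit across candidate soft powers."""

    table: pd.DataFrame  # power, signed_r2, slope, k_mean, k_median, k_max, degenerate
    chosen_power: int | None  # None when every candidate fit is degenerate
    target_r2: float

    def __repr__(self) -> str:  # pragma: no cover
        return (f"PowerFitResult(chosen_power={self.chosen_power}, "
                f"target_r2={self.target_r2}, n_powers={len(self.table)})")


@dataclass
class Network:
    adjacency: pd.DataFrame
    power: int
    network_type: str = "signed-hybrid"
    tom: pd.DataFrame | None = None
    diss_tom: pd.DataFrame | None = None


def bicor(
    expr: pd.DataFrame, max_p_outliers: float = 0.1
) -> CorrelationMatrix:
    """Biweight midcorrelation between all gene pairs.

    For each gene, samples are weighted by Tukey's biweight around the median
    with scale 9 * MAD; before weighting, each side of the scaled deviations
    ``u`` is rescaled so that at most ``max_p_outliers`` of the samples per
    side fall outside |u| >= 1 (i.e. receive zero weight).  Genes with zero
    MAD fall back to Pearson and are flagged.

    Parameters
    ----------
    expr : genes x samples matrix (log scale).
    max_p_outliers : maximum fraction of samples excluded on each side.
    """
    if expr.shape[1] < 4:
        raise ValueError("biweight midcorrelation needs at least 4 samples")
    if not np.isfinite(expr.values).all():
        raise ValueError("expression matrix contains non-finite values")
    if not (0 < max_p_outliers <= 0.5):
        raise ValueError("max_p_outliers must be in (0, 0.5]")
    if expr.shape[0] > MAX_DENSE_GENES:
        raise ValueError(
            f"{expr.shape[0]} genes exceeds the dense-matrix cap of "
            f"{MAX_DENSE_GENES}; pre-filter the expression matrix"
        )
    x = expr.values.astype(float)
    a, fallback = _bicor_terms(x, max_p_outliers)
    r = a @ a.T
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(
        values=pd.DataFrame(r, index=expr.index, columns=expr.index),
        method="bicor",
        max_p_outliers=max_p_outliers,
        pearson_fallback=tuple(expr.index[fallback]),
    )


def bicor_pair(x: np.ndarray, y: np.ndarray, max_p_outliers: float = 0.1) -> float:
    """Biweight midcorrelation of two vectors (convenience wrapper)."""
    m = np.vstack([x, y]).astype(float)
    a, _ = _bicor_terms(m, max_p_outliers)
    return float(np.clip(a[0] @ a[1], -1.0, 1.0))


def _bicor_terms(x: np.ndarray, max_p_outliers: float):
    """Row-wise normalized biweight terms; rows with zero MAD use Pearson."""
    med = np.median(x, axis=1, keepdims=True)
    dev = x - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    fallback = (mad[:, 0] == 0)
    safe_mad = np.where(mad == 0, 1.0, mad)
    u = dev / (9.0 * safe_mad)

    # side-specific rescaling: the max_p_outliers quantile of u maps to -1
    # (and 1 - max_p_outliers to +1) whenever it would otherwise lie beyond.
    ql = np.quantile(u, max_p_outliers, axis=1, keepdims=True)
    qh = np.quantile(u, 1.0 - max_p_outliers, axis=1, keepdims=True)
    scale_neg = np.where(ql < -1.0, -ql, 1.0)
    scale_pos = np.where(qh > 1.0, qh, 1.0)
    u = np.where(u < 0, u / scale_neg, u / scale_pos)

    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    a = dev * w
    # Pearson fallback rows: plain centered values
    if fallback.any():
        cen = x - x.mean(axis=1, keepdims=True)
        a[fallback] = cen[fallback]
    norm = np.sqrt((a**2).sum(axis=1, keepdims=True))
    norm[norm == 0] = 1.0
    return a / norm, fallback


def adjacency_signed_hybrid(cor: CorrelationMatrix | pd.DataFrame, power: int) -> Network:
    """Signed-hybrid adjacency: ``a_ij = cor_ij ** power`` if positive, else 0."""
    if power < 1:
        raise ValueError("power must be >= 1")
    values = cor.values if isinstance(cor, CorrelationMatrix) else cor
    if values.shape[0] > MAX_DENSE_GENES:
        raise ValueError(
            f"{values.shape[0]} genes exceeds the dense-matrix cap of "
            f"{MAX_DENSE_GENES}; pre-filter the expression matrix"
        )
    c = values.values
    a = np.where(c > 0, c, 0.0) ** float(power)
    np.fill_diagonal(a, 1.0)
    return Network(
        adjacency=pd.DataFrame(a, index=values.index, columns=values.columns),
        power=int(power),
    )


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float, bool]:
    """Signed R^2 of the log-log degree-distribution fit.

    Bins connectivity into ``n_bins`` equal-width bins, regresses
    log10(frequency) on log10(mean k per nonempty bin) and returns
    ``(-sign(slope) * R^2, slope, degenerate)``.  A fit on fewer than three
    informative bins (e.g. all genes equally connected) is degenerate.
    """
    k = np.asarray(k, dtype=float)
    if np.all(k == 0):
        raise ValueError("network has no connectivity at this power")
    spread = k.max() - k.min()
    if spread < 1e-12 * max(k.max(), 1.0):
        return np.nan, np.nan, True
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(which, minlength=n_bins).astype(float)
    sums = np.bincount(which, weights=k, minlength=n_bins)
    ok = freq > 0
    mean_k = np.where(ok, sums / np.maximum(freq, 1), np.nan)
    ok &= mean_k > 0
    if ok.sum() < 3:
        return np.nan, np.nan, True
    lx = np.log10(mean_k[ok])
    ly = np.log10(freq[ok] / freq.sum())
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = ((ly - ly.mean()) ** 2).sum()
    if ss_tot == 0:
        return np.nan, np.nan, True
    r2 = 1.0 - (resid**2).sum() / ss_tot
    return float(-np.sign(slope) * r2), float(slope), False


def pick_soft_threshold(
    cor: CorrelationMatrix | pd.DataFrame,
    powers: tuple[int, ...] = tuple(range(1, 31)),
    target_r2: float = 0.85,
    n_bins: int = 10,
) -> PowerFitResult:
    """Choose the soft power by the scale-free topology criterion.

    For each candidate power the signed-hybrid connectivity distribution is
    fit against a power law; the chosen power is the smallest whose signed
    R^2 reaches ``target_r2``, or the argmax of signed R^2 if none does.
    Degenerate fits (near-constant connectivity) are flagged and never chosen.
    """
    values = cor.values if isinstance(cor, CorrelationMatrix) else cor
    if values.shape[0] < n_bins:
        raise ValueError("need at least n_bins genes for the degree fit")
    c = values.values.copy()
    np.fill_diagonal(c, 0.0)
    pos = np.where(c > 0, c, 0.0)
    rows = []
    for beta in powers:
        k = (pos ** float(beta)).sum(axis=1)
        if np.all(k == 0):
            raise ValueError(f"network has no positive edges at power {beta}")
        r2, slope, degenerate = scale_free_fit(k, n_bins=n_bins)
        rows.append({
            "power": int(beta), "signed_r2": r2, "slope": slope,
            "k_mean": float(k.mean()), "k_median": float(np.median(k)),
            "k_max": float(k.max()), "degenerate": degenerate,
        })
    table = pd.DataFrame(rows)
    usable = table[~table["degenerate"]]
    if usable.empty:
        # every fit degenerate (e.g. all genes equally connected): nothing
        # can be chosen, but the flags are still reported
        return PowerFitResult(table=table, chosen_power=None, target_r2=target_r2)
    hit = usable[usable["signed_r2"] >= target_r2]
    if len(hit):
        chosen = int(hit["power"].iloc[0])
    else:
        chosen = int(usable.loc[usable["signed_r2"].idxmax(), "power"])
    return PowerFitResult(table=table, chosen_power=chosen, target_r2=target_r2)


def recommended_power(n_samples: int, network_type: str = "signed-hybrid") -> int:
    """Field-standard soft power by sample size, for when no candidate power
    reaches the scale-free fit target.

    For unsigned and signed-hybrid networks the convention is 9 below 20
    samples, 8 up to 30, 7 up to 40 and 6 beyond; fully signed networks use
    twice these values.
    """
    if n_samples < 20:
        p = 9
    elif n_samples < 30:
        p = 8
    elif n_samples < 40:
        p = 7
    else:
        p = 6
    return 2 * p if network_type == "signed" else p


def tom(net: Network) -> Network:
    """Topological overlap of the adjacency; fills ``tom`` and ``diss_tom``.

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    connectivity k excluding the diagonal; TOM_ii = 1.  A vanishing
    denominator can only occur for two isolated genes, where the numerator
    also vanishes; such entries are set to 0.
    """
    a = net.adjacency.values.astype(float).copy()
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (shared + a) / denom
    t[denom <= 1e-12] = 0.0
    t = 0.5 * (t + t.T)  # symmetrize away float round-off
    np.fill_diagonal(t, 1.0)
    idx = net.adjacency.index
    net.tom = pd.DataFrame(t, index=idx, columns=idx)
    net.diss_tom = pd.DataFrame(1.0 - t, index=idx, columns=idx)
    return net
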