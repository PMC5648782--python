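"""Module detection from TOM dissimilarity and module-level statistics.

Modules are branches of the average-linkage dendrogram of 1 - TOM, found by
a deterministic adaptive branch decomposition (a height-profile "tree"
variant of dynamic tree cut): a static cut close to the dendrogram top
yields candidate branches, branches are recursively split wherever both
children are large enough and separated from their join by a clear height
gap, and a terminal branch is accepted as a module only when it is both
large enough and tight — its own merge height sits well below the height at
which it joins the rest of the tree.  Each module is summarized by its
eigengene (first principal component of the standardized member expression),
similar modules are merged by eigengene correlation, and genes are ranked by
module membership kME.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests


@dataclass
class Dendrogram:
    """Agglomerative tree: scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray
    labels: pd.Index
    method: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


@dataclass
class ModuleSet:
    labels: pd.Series  # gene -> module id, 0 = unassigned
    eigengenes: pd.DataFrame  # modules x samples, unit-norm rows
    variance_explained: pd.Series
    kme: pd.DataFrame | None = None
    kme_p: pd.DataFrame | None = None
    merge_history: list = field(default_factory=list)

    @property
    def module_ids(self) -> list[int]:
        return [int(m) for m in self.eigengenes.index]


@dataclass
class ModuleTraitResult:
    r: pd.DataFrame  # modules x traits
    p: pd.DataFrame
    fdr: pd.DataFrame
    n_samples: int


def _check_dissimilarity(diss: pd.DataFrame) -> np.ndarray:
    d = diss.values.astype(float)
    if np.isnan(d).any():
        raise ValueError("dissimilarity contains NaN")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return d


def hclust_average(diss: pd.DataFrame) -> Dendrogram:
    """Average-linkage hierarchical clustering of a dissimilarity matrix."""
    d = _check_dissimilarity(diss)
    z = linkage(squareform(d, checks=False), method="average")
    return Dendrogram(linkage=z, labels=diss.index, method="average")


def hclust_complete(diss: pd.DataFrame) -> Dendrogram:
    """Complete-linkage hierarchical clustering of a dissimilarity matrix."""
    d = _check_dissimilarity(diss)
    z = linkage(squareform(d, checks=False), method="complete")
    return Dendrogram(linkage=z, labels=diss.index, method="complete")


def cut_dynamic(
    dend: Dendrogram,
    min_module_size: int = 50,
    deep_split: int = 2,
    cut_height_frac: float = 0.99,
) -> pd.Series:
    """Adaptive branch decomposition of a dendrogram into modules.

    The tree is first cut at ``cut_height_frac`` of its maximum merge height;
    each resulting branch is recursively split into its children whenever
    both children hold at least ``min_module_size`` leaves and both sit a
    clear height gap below the join — at least
    ``gap_frac * (join height - mean merge height inside the branch)`` with
    ``gap_frac = 0.3 - 0.05 * deep_split``, so the gap requirement adapts to
    each branch's own height profile.  A terminal branch becomes a module
    iff it has >= ``min_module_size`` leaves and the height at which it
    joins the rest of the tree exceeds its own merge height by that same
    branch-relative gap: tight, well-separated branches are kept, while
    loosely attached aggregates (the hallmark of a structureless
    dissimilarity, whose merge heights pile up just below the join) are left
    unassigned (label 0).  Module ids are assigned by decreasing size (ties
    by smallest leaf index), so the output is fully deterministic.
    """
    n = dend.n_leaves
    if min_module_size > n:
        raise ValueError("min_module_size exceeds the number of genes")
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    z = dend.linkage
    cut_height = cut_height_frac * z[:, 2].max()
    gap_frac = 0.3 - 0.05 * deep_split

    n_nodes = n + len(z)
    child = np.full((n_nodes, 2), -1, dtype=int)
    height = np.zeros(n_nodes)
    size = np.ones(n_nodes, dtype=int)
    parent_h = np.full(n_nodes, np.inf)
    h_sum = np.zeros(n_nodes)  # sum of merge heights inside the subtree
    h_cnt = np.zeros(n_nodes, dtype=int)
    for i in range(len(z)):
        a, b = int(z[i, 0]), int(z[i, 1])
        node = n + i
        child[node] = (a, b)
        height[node] = z[i, 2]
        size[node] = size[a] + size[b]
        parent_h[a] = parent_h[b] = z[i, 2]
        h_sum[node] = h_sum[a] + h_sum[b] + z[i, 2]
        h_cnt[node] = h_cnt[a] + h_cnt[b] + 1

    # top nodes of the static cut: maximal nodes merged at <= cut_height
    tops = [
        node for node in range(n_nodes)
        if height[node] <= cut_height and parent_h[node] > cut_height
    ]

    def gap_ok(node: int, join: float) -> bool:
        mean_int = h_sum[node] / h_cnt[node] if h_cnt[node] else height[node]
        return join - height[node] >= gap_frac * max(join - mean_int, 1e-300)

    def decompose(node: int, join: float) -> list[int]:
        """Accepted module nodes inside the branch rooted at ``node``.

        ``join`` is the height at which the branch attaches to the rest of
        the tree.  Order of precedence: split into two clearly distinct
        large sub-branches; accept the branch whole if it hangs clearly
        below its join; otherwise peel stragglers (small late-attaching
        side branches) off the top and retry on the remaining core, keeping
        the original join.
        """
        out, stack = [], [(node, join)]
        while stack:
            v, j = stack.pop()
            if size[v] < min_module_size:
                continue
            a, b = child[v]
            if (
                a >= 0
                and size[a] >= min_module_size
                and size[b] >= min_module_size
                and gap_ok(a, height[v])
                and gap_ok(b, height[v])
            ):
                stack.append((a, height[v]))
                stack.append((b, height[v]))
                continue
            if gap_ok(v, j):
                out.append(v)
                continue
            if a >= 0:
                big, small = (a, b) if size[a] >= size[b] else (b, a)
                if size[small] < min_module_size <= size[big]:
                    stack.append((big, j))
        return out

    def leaves(node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                stack.extend(child[v])
        return out

    accepted = []
    for top in tops:
        join = parent_h[top] if np.isfinite(parent_h[top]) else cut_height
        accepted.extend(decompose(top, join))

    lv_sets = [sorted(leaves(node)) for node in accepted]
    order = sorted(range(len(accepted)), key=lambda i: (-len(lv_sets[i]), lv_sets[i][0]))
    labels = np.zeros(n, dtype=int)
    for new_id, i in enumerate(order, start=1):
        labels[lv_sets[i]] = new_id
    return pd.Series(labels, index=dend.labels, name="module")


def module_eigengene(
    expr: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """First principal component of each module's standardized expression.

    Member gene profiles are standardized to zero mean and unit variance;
    the eigengene is the first right singular vector across samples (unit
    norm), oriented so that its average correlation with the member genes is
    non-negative.  Returns (eigengenes, variance explained).  Constant genes
    inside a module are excluded with a warning.
    """
    import warnings

    labels = labels.reindex(expr.index)
    modules = sorted(int(m) for m in labels.unique() if m != 0)
    me_rows, ve = [], []
    for m in modules:
        members = expr.loc[labels == m]
        sd = members.std(axis=1, ddof=1)
        if (sd == 0).any():
            warnings.warn(f"module {m}: excluding {(sd == 0).sum()} constant gene(s)")
            members = members.loc[sd > 0]
            sd = sd.loc[sd > 0]
        if members.shape[0] < 2:
            raise ValueError(f"module {m} has fewer than 2 usable genes")
        xs = members.sub(members.mean(axis=1), axis=0).div(sd, axis=0).values
        _, s, vt = np.linalg.svd(xs, full_matrices=False)
        eig = vt[0]
        # orient: mean correlation with members >= 0
        mean_cor = np.mean([_pearson(row, eig) for row in xs])
        if mean_cor < 0:
            eig = -eig
        me_rows.append(eig)
        ve.append(s[0] ** 2 / (s**2).sum())
    idx = pd.Index(modules, name="module")
    return (
        pd.DataFrame(me_rows, index=idx, columns=expr.columns),
        pd.Series(ve, index=idx, name="variance_explained"),
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return np.nan
    return float(xc @ yc / denom)


def merge_modules(
    expr: pd.DataFrame,
    labels: pd.Series,
    me_diss_threshold: float = 0.1,
) -> ModuleSet:
    """Iteratively merge modules whose eigengenes are nearly identical.

    At each round, modules whose eigengene dissimilarity ``1 - cor`` falls
    strictly below the threshold are grouped by transitive closure, each group
    collapses into one module (keeping the smallest id), and eigengenes are
    recomputed; rounds repeat until no pair is below the threshold.  The merge
    history records each round's groups.
    """
    labels = labels.reindex(expr.index).copy()
    history: list[list[list[int]]] = []
    while True:
        me, ve = module_eigengene(expr, labels)
        ids = list(me.index)
        if len(ids) <= 1:
            break
        z = me.values
        zc = z - z.mean(axis=1, keepdims=True)
        norm = np.sqrt((zc**2).sum(axis=1, keepdims=True))
        cor = (zc / norm) @ (zc / norm).T
        diss = 1.0 - cor
        close = diss < me_diss_threshold
        np.fill_diagonal(close, False)
        if not close.any():
            break
        groups = _components(close)
        round_groups = []
        for comp in groups:
            if len(comp) < 2:
                continue
            members = sorted(ids[i] for i in comp)
            keep = members[0]
            round_groups.append(members)
            labels[labels.isin(members)] = keep
        history.append(round_groups)
    me, ve = module_eigengene(expr, labels)
    # relabel to consecutive ids by decreasing size
    sizes = labels[labels != 0].value_counts()
    remap = {int(old): i + 1 for i, old in enumerate(sizes.index)}
    labels = labels.map(lambda m: remap.get(int(m), 0))
    me.index = pd.Index([remap[int(m)] for m in me.index], name="module")
    ve.index = me.index
    me = me.sort_index()
    ve = ve.sort_index()
    return ModuleSet(
        labels=labels, eigengenes=me, variance_explained=ve, merge_history=history
    )


def _components(adj: np.ndarray) -> list[list[int]]:
    n = adj.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for u in np.nonzero(adj[v])[0]:
                if not seen[u]:
                    seen[u] = True
                    stack.append(u)
        comps.append(sorted(comp))
    return comps


def correlation_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided Student-t p-value for a Pearson correlation with n samples."""
    r = np.clip(np.asarray(r, dtype=float), -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return 2.0 * t_dist.sf(np.abs(t), df=n - 2)


def module_trait_cor(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    fdr_family: str = "per_trait",
) -> ModuleTraitResult:
    """Pearson correlation of module eigengenes with numeric sample traits.

    P-values come from the exact Student-t transform with n - 2 degrees of
    freedom; Benjamini-Hochberg adjustment is applied within each trait
    family (default) or globally.  Constant traits yield missing values.
    """
    n = eigengenes.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples")
    if list(traits.index) != list(eigengenes.columns):
        traits = traits.loc[eigengenes.columns]
    r = pd.DataFrame(index=eigengenes.index, columns=traits.columns, dtype=float)
    for trait in traits.columns:
        tv = traits[trait].values.astype(float)
        if np.std(tv) == 0:
            r[trait] = np.nan
            continue
        for m in eigengenes.index:
            r.loc[m, trait] = _pearson(eigengenes.loc[m].values, tv)
    p = pd.DataFrame(
        correlation_pvalue(r.values, n), index=r.index, columns=r.columns
    )
    p[r.isna()] = np.nan
    fdr = p.copy()
    if fdr_family == "per_trait":
        for trait in p.columns:
            mask = p[trait].notna()
            if mask.any():
                fdr.loc[mask, trait] = multipletests(
                    p.loc[mask, trait].values, method="fdr_bh"
                )[1]
    elif fdr_family == "global":
        mask = p.notna().values.ravel()
        flat = p.values.ravel()
        adj = np.full_like(flat, np.nan)
        adj[mask] = multipletests(flat[mask], method="fdr_bh")[1]
        fdr = pd.DataFrame(adj.reshape(p.shape), index=p.index, columns=p.columns)
    else:
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    return ModuleTraitResult(r=r, p=p, fdr=fdr, n_samples=n)


def kme(expr: pd.DataFrame, eigengenes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Module membership: correlation of every gene with every eigengene.

    Returns (kME, p) where p is the Student-t correlation p-value.  All genes
    get a kME column for every module, including unassigned genes.
    """
    n = expr.shape[1]
    x = expr.values.astype(float)
    xc = x - x.mean(axis=1, keepdims=True)
    xn = np.sqrt((xc**2).sum(axis=1, keepdims=True))
    xn[xn == 0] = np.nan
    e = eigengenes.values
    ec = e - e.mean(axis=1, keepdims=True)
    en = np.sqrt((ec**2).sum(axis=1, keepdims=True))
    r = (xc / xn) @ (ec / en).T
    r = np.clip(r, -1, 1)
    p = correlation_pvalue(r, n)
    cols = eigengenes.index
    return (
        pd.DataFrame(r, index=expr.index, columns=cols),
        pd.DataFrame(p, index=expr.index, columns=cols),
    )


def hub_genes(
    kme_values: pd.DataFrame,
    kme_p: pd.DataFrame,
    labels: pd.Series,
    r_min: float = 0.9,
    p_max: float = 1e-6,
) -> dict[int, list[str]]:
    """Intramodular hubs: member genes with kME > r_min and p < p_max."""
    labels = labels.reindex(kme_values.index)
    hubs: dict[int, list[str]] = {}
    for m in kme_values.columns:
        members = labels.index[(labels == int(m)).values]
        sel = (kme_values.loc[members, m] > r_min) & (kme_p.loc[members, m] < p_max)
        hubs[int(m)] = sorted(members[sel.values])
    return hubs
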