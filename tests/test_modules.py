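"""Dendrograms, dynamic cut, eigengenes, merging, trait correlation, hubs."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from coexnet import (
    cut_dynamic, hclust_average, hclust_complete, hub_genes, kme,
    merge_modules, module_eigengene, module_trait_cor,
)
from coexnet.modules import correlation_pvalue


def brute_force_linkage(d, method):
    """O(n^3) agglomeration oracle returning the merge height sequence."""
    d = d.copy().astype(float)
    clusters = {i: [i] for i in range(d.shape[0])}
    heights = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                pairs = [d[i, j] for i in clusters[a] for j in clusters[b]]
                h = np.mean(pairs) if method == "average" else max(pairs)
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return np.array(heights)


def random_dissimilarity(rng, n):
    d = rng.uniform(0.1, 1.0, (n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d)


def block_dissimilarity(sizes, within=0.05, between=1.0):
    n = sum(sizes)
    d = np.full((n, n), between)
    start = 0
    for s in sizes:
        d[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d)


class TestHclust:
    def test_two_blocks_final_height(self):
        d = block_dissimilarity([3, 3], within=0.0, between=1.0)
        dend = hclust_average(d)
        assert dend.heights[-1] == pytest.approx(1.0)

    @pytest.mark.parametrize("method,fn", [
        ("average", hclust_average), ("complete", hclust_complete)])
    def test_toy_matches_brute_force(self, rng, method, fn):
        for n in (5, 6):
            d = random_dissimilarity(rng, n)
            dend = fn(d)
            assert np.allclose(
                np.sort(dend.heights), np.sort(brute_force_linkage(d.values, method)),
                atol=1e-12)

    def test_leaf_permutation_gives_isomorphic_tree(self, rng):
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        d = random_dissimilarity(rng, 8)
        perm = rng.permutation(8)
        dp = pd.DataFrame(d.values[np.ix_(perm, perm)])
        c1 = squareform(cophenet(hclust_average(d).linkage))
        c2 = squareform(cophenet(hclust_average(dp).linkage))
        assert np.allclose(c1[np.ix_(perm, perm)], c2, atol=1e-12)

    def test_nan_rejected(self):
        d = block_dissimilarity([2, 2])
        d.iloc[0, 1] = d.iloc[1, 0] = np.nan
        with pytest.raises(ValueError):
            hclust_average(d)

    def test_ultrametric_reproduced_exactly(self):
        # heights 0.2 then 0.6 in a nested ultrametric
        d = pd.DataFrame([[0, .2, .6, .6], [.2, 0, .6, .6],
                          [.6, .6, 0, .2], [.6, .6, .2, 0]], dtype=float)
        dend = hclust_complete(d)
        assert np.allclose(np.sort(dend.heights), [0.2, 0.2, 0.6])


class TestCutDynamic:
    def test_three_clean_blocks(self):
        d = block_dissimilarity([100, 100, 100])
        labels = cut_dynamic(hclust_average(d), min_module_size=50)
        assert labels.nunique() == 3
        assert (labels != 0).all()
        # each block is one module
        for s in range(3):
            assert labels.iloc[s * 100:(s + 1) * 100].nunique() == 1

    def test_min_size_exceeding_branches_unassigns_all(self):
        d = block_dissimilarity([40, 40])
        labels = cut_dynamic(hclust_average(d), min_module_size=50)
        assert (labels == 0).all()

    def test_min_size_above_n_rejected(self):
        d = block_dissimilarity([10, 10])
        with pytest.raises(ValueError):
            cut_dynamic(hclust_average(d), min_module_size=50)

    def test_structureless_dissimilarity_mostly_unassigned(self, rng):
        # iid dissimilarities have no branch structure
        d = random_dissimilarity(rng, 400)
        d2 = (d + 0.9) / 1.9  # push into the high-dissimilarity regime
        d2 = d2 * (1 - np.eye(400))
        labels = cut_dynamic(hclust_average(pd.DataFrame(d2)), min_module_size=50)
        assert (labels != 0).mean() <= 0.10

    def test_deterministic(self, rng):
        d = random_dissimilarity(rng, 60)
        l1 = cut_dynamic(hclust_average(d), min_module_size=10)
        l2 = cut_dynamic(hclust_average(d), min_module_size=10)
        assert l1.equals(l2)


class TestEigengene:
    def test_identical_genes_explain_everything(self, rng):
        profile = rng.normal(size=10)
        expr = pd.DataFrame(np.tile(profile, (5, 1)),
                            index=[f"g{i}" for i in range(5)])
        labels = pd.Series(1, index=expr.index)
        me, ve = module_eigengene(expr, labels)
        assert ve.iloc[0] == pytest.approx(1.0)
        zp = (profile - profile.mean()) / profile.std(ddof=1)
        r = np.corrcoef(me.iloc[0], zp)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert r > 0  # oriented towards the members

    def test_sign_flip_invariance(self, rng):
        expr = pd.DataFrame(rng.normal(size=(8, 12)))
        labels = pd.Series(1, index=expr.index)
        me1, _ = module_eigengene(expr, labels)
        me2, _ = module_eigengene(-expr, labels)
        assert np.allclose(me1.values, -me2.values, atol=1e-9) or \
            np.allclose(me1.values, me2.values, atol=1e-9)
        # orientation: mean correlation with members is non-negative either way
        for expr_, me_ in ((expr, me1), (-expr, me2)):
            cors = [np.corrcoef(expr_.iloc[i], me_.iloc[0])[0, 1]
                    for i in range(len(expr_))]
            assert np.mean(cors) >= 0

    def test_constant_gene_excluded_with_warning(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 8)))
        expr.iloc[0] = 2.0
        labels = pd.Series(1, index=expr.index)
        with pytest.warns(UserWarning, match="constant"):
            me, ve = module_eigengene(expr, labels)
        assert me.shape == (1, 8)

    def test_planted_trajectory_recovered(self, default_sim, filtered_expr):
        _, _, truth, _ = default_sim
        labels = truth.labels.reindex(filtered_expr.index)
        me, _ = module_eigengene(filtered_expr, labels)
        for m in me.index:
            traj = truth.trajectories.loc[m].values
            r = np.corrcoef(me.loc[m].values, traj)[0, 1]
            assert abs(r) >= 0.95


class TestMerge:
    def _expr_with_trajectories(self, rng, trajs, genes_per=20, noise=0.05):
        rows, labels = [], []
        for m, t in enumerate(trajs, start=1):
            for _ in range(genes_per):
                rows.append(t + rng.normal(0, noise, len(t)))
                labels.append(m)
        expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])
        return expr, pd.Series(labels, index=expr.index)

    def test_identical_trajectories_merge(self, rng):
        t = rng.normal(size=10)
        expr, labels = self._expr_with_trajectories(rng, [t, t])
        mods = merge_modules(expr, labels, me_diss_threshold=0.1)
        assert len(mods.eigengenes) == 1
        assert mods.merge_history

    def test_orthogonal_trajectories_do_not_merge(self, rng):
        t1 = np.array([1.0, -1, 1, -1, 1, -1, 1, -1, 1, -1])
        t2 = np.array([1.0, 1, -1, -1, 1, 1, -1, -1, 1, 1])
        expr, labels = self._expr_with_trajectories(rng, [t1, t2])
        mods = merge_modules(expr, labels, me_diss_threshold=0.1)
        assert len(mods.eigengenes) == 2
        assert not mods.merge_history

    def test_transitive_closure_of_threshold_rule(self, rng):
        # chain of five trajectories: consecutive ones nearly identical in
        # pairs (1,2) and (4,5); 3 is on its own
        base = rng.normal(size=12)
        other = rng.normal(size=12)
        third = rng.normal(size=12)
        trajs = [base, base + rng.normal(0, 0.02, 12),
                 third,
                 other, other + rng.normal(0, 0.02, 12)]
        expr, labels = self._expr_with_trajectories(rng, trajs, noise=0.01)
        me, _ = module_eigengene(expr, labels)
        cor = np.corrcoef(me.values)
        close = (1 - cor) < 0.1
        np.fill_diagonal(close, False)
        # brute-force transitive closure
        groups = []
        seen = set()
        for i in range(5):
            if i in seen:
                continue
            comp, stack = set(), [i]
            while stack:
                v = stack.pop()
                if v in comp:
                    continue
                comp.add(v)
                stack.extend(np.nonzero(close[v])[0])
            seen |= comp
            groups.append(frozenset(comp))
        mods = merge_modules(expr, labels, me_diss_threshold=0.1)
        got = {}
        for g, m in mods.labels.items():
            got.setdefault(m, set()).add(labels[g] - 1)
        assert {frozenset(v) for v in got.values()} == set(groups)

    def test_idempotent_at_fixed_point(self, rng):
        t1 = rng.normal(size=10)
        t2 = rng.normal(size=10)
        expr, labels = self._expr_with_trajectories(rng, [t1, t1, t2])
        mods = merge_modules(expr, labels, me_diss_threshold=0.1)
        again = merge_modules(expr, mods.labels, me_diss_threshold=0.1)
        assert again.labels.equals(mods.labels)
        assert not again.merge_history


def bh_oracle(p):
    """Step-up Benjamini-Hochberg, written as the literal procedure."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


class TestModuleTrait:
    def test_eigengene_equal_to_day(self, rng):
        day = np.array([1.0, 1, 2, 2, 3, 3, 4, 4, 5, 5, 6, 6, 7, 8, 9])
        me = pd.DataFrame([day], index=pd.Index([1], name="module"),
                          columns=[f"s{i}" for i in range(15)])
        traits = pd.DataFrame({"day": day}, index=me.columns)
        res = module_trait_cor(me, traits)
        assert res.r.iloc[0, 0] == pytest.approx(1.0)
        assert res.p.iloc[0, 0] < 1e-10

    def test_p_value_matches_scipy_pearsonr(self, rng):
        for _ in range(10):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            r, p = pearsonr(x, y)
            assert correlation_pvalue(np.array([r]), 15)[0] == pytest.approx(p, rel=1e-9)

    def test_strong_module_magnitude(self):
        # |r| = 0.87 at n = 15: two-sided p close to 2.4e-5 (t = 6.36, 13 df)
        p = correlation_pvalue(np.array([0.87]), 15)[0]
        assert 1e-5 < p < 5e-5

    def test_fdr_is_bh(self, rng):
        me = pd.DataFrame(rng.normal(size=(10, 15)),
                          index=pd.Index(range(1, 11), name="module"))
        traits = pd.DataFrame({"day": rng.normal(size=15),
                               "clade": rng.normal(size=15)},
                              index=me.columns)
        res = module_trait_cor(me, traits)
        for trait in ("day", "clade"):
            assert np.allclose(res.fdr[trait].values,
                               bh_oracle(res.p[trait].values), atol=1e-12)
            assert (res.fdr[trait] >= res.p[trait] - 1e-15).all()

    def test_constant_trait_reported_missing(self, rng):
        me = pd.DataFrame(rng.normal(size=(3, 12)),
                          index=pd.Index(range(1, 4), name="module"))
        traits = pd.DataFrame({"flat": np.ones(12)}, index=me.columns)
        res = module_trait_cor(me, traits)
        assert res.r["flat"].isna().all()


class TestKmeHubs:
    def test_member_identical_to_eigengene_is_hub(self, rng):
        profile = rng.normal(size=15)
        expr = pd.DataFrame(np.tile(profile, (6, 1)) +
                            rng.normal(0, 1e-9, (6, 15)),
                            index=[f"g{i}" for i in range(6)])
        labels = pd.Series(1, index=expr.index)
        me, _ = module_eigengene(expr, labels)
        k, p = kme(expr, me)
        hubs = hub_genes(k, p, labels)
        assert set(hubs[1]) == set(expr.index)
        assert k.values.max() == pytest.approx(1.0)

    def test_kme_point_nine_is_not_hub_at_fifteen_samples(self):
        # at n = 15, |kME| = 0.9 has p ~ 4.9e-6 > 1e-6: both rules together
        # exclude a gene sitting exactly at the kME cutoff
        p = correlation_pvalue(np.array([0.9]), 15)[0]
        assert 1e-6 < p < 1e-5

    def test_background_genes_rarely_hub(self, default_sim, filtered_expr):
        from coexnet import filter_abundance, tmm_normalize

        _, cm, truth, _ = default_sim
        em = tmm_normalize(filter_abundance(cm))
        labels_f = truth.labels.reindex(filtered_expr.index)
        me, _ = module_eigengene(filtered_expr, labels_f)
        labels_all = truth.labels.reindex(em.values.index)
        background = em.values.loc[(labels_all == 0).values]
        k, p = kme(background, me)
        # unstructured background genes essentially never reach hub-level kME
        for m in me.index:
            assert (k[m] < 0.9).mean() >= 0.99


@pytest.fixture(scope="session")
def filtered_expr(default_sim):
    from coexnet import filter_abundance, filter_variance, tmm_normalize

    _, cm, _, _ = default_sim
    em = tmm_normalize(filter_abundance(cm))
    values, _ = filter_variance(em.values)
    return values
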