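"""Over-representation analysis of gene sets against annotation terms.

Provides the classical one-sided hypergeometric test with Benjamini-Hochberg
control, a length-bias-aware variant that models the probability of a gene
entering the test set as a monotone function of its transcript length and
tests each term with the Wallenius noncentral hypergeometric distribution,
and a rollup of significant terms to slim summary categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, nchypergeom_wallenius
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationMap:
    gene_to_terms: dict[str, frozenset]
    term_names: dict[str, str] = field(default_factory=dict)
    slim_map: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs, term_names=None, slim_map=None) -> "AnnotationMap":
        g2t: dict[str, set] = {}
        for gene, term in pairs:
            g2t.setdefault(str(gene), set()).add(str(term))
        return cls(
            gene_to_terms={g: frozenset(t) for g, t in g2t.items()},
            term_names=dict(term_names or {}),
            slim_map=dict(slim_map or {}),
        )

    @classmethod
    def from_tsv(cls, path) -> "AnnotationMap":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["gene", "term"], dtype=str)
        return cls.from_pairs(df.itertuples(index=False))

    def terms_in(self, genes) -> dict[str, set]:
        out: dict[str, set] = {}
        for g in genes:
            for t in self.gene_to_terms.get(str(g), ()):
                out.setdefault(t, set()).add(g)
        return out


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # per term: k_test, n_test, k_universe, n_universe, p, fdr, significant
    alpha: float
    method: str

    @property
    def significant_terms(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def _check_sets(test_set, universe):
    test_set, universe = set(map(str, test_set)), set(map(str, universe))
    if not test_set:
        raise ValueError("test set is empty")
    if not test_set <= universe:
        raise ValueError("test set must be a subset of the universe")
    return test_set, universe


def overrepresentation(
    test_set, universe, annot: AnnotationMap, alpha: float = 0.05
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation test per term, with BH.

    For a term annotating K of the N universe genes, the p-value is the upper
    hypergeometric tail P(X >= k) of drawing k annotated genes in a test set
    of size n.  Terms absent from the universe are skipped.
    """
    test_set, universe = _check_sets(test_set, universe)
    by_term_u = annot.terms_in(universe)
    by_term_t = annot.terms_in(test_set)
    n_univ, n_test = len(universe), len(test_set)
    rows = []
    for term in sorted(by_term_u):
        big_k = len(by_term_u[term])
        k = len(by_term_t.get(term, ()))
        p = float(hypergeom.sf(k - 1, n_univ, big_k, n_test))
        rows.append({"term": term, "k_test": k, "n_test": n_test,
                     "k_universe": big_k, "n_universe": n_univ, "p": p})
    table = pd.DataFrame(rows).set_index("term")
    table["fdr"] = multipletests(table["p"].values, method="fdr_bh")[1]
    table["significant"] = table["fdr"] < alpha
    return EnrichmentResult(table=table, alpha=alpha, method="hypergeometric")


def length_bias_weights(
    de_flags: pd.Series, lengths: pd.Series, n_bins: int = 30
) -> pd.Series:
    """Monotone selection-probability weight per gene as a function of length.

    Genes are grouped into roughly equal-count length bins; the per-bin
    selection fraction is smoothed by increasing isotonic regression
    (pool-adjacent-violators) over the bin median lengths and mapped back to
    genes.  Weights are floored at a small positive value.
    """
    de = de_flags.astype(bool)
    if de.all() or not de.any():
        raise ValueError("de_flags must contain both selected and unselected genes")
    lengths = lengths.loc[de.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("lengths must be positive")
    n_bins = min(n_bins, max(2, len(de) // 5))
    ranks = lengths.rank(method="first")
    bins = np.ceil(ranks / len(de) * n_bins).astype(int)
    centers, fracs = [], []
    for b in sorted(bins.unique()):
        sel = bins == b
        centers.append(float(lengths[sel].median()))
        fracs.append(float(de[sel].mean()))
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(centers, fracs)
    w = iso.predict(lengths.values)
    w = np.maximum(w, 1e-6)
    return pd.Series(w, index=de.index, name="weight")


def wallenius_test(
    de_flags: pd.Series,
    annot: AnnotationMap,
    weights: pd.Series | None = None,
    lengths: pd.Series | None = None,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Length-bias-corrected over-representation via Wallenius' distribution.

    The universe is the index of ``de_flags``; the test set is where the flag
    is true.  Each term's p-value is the upper tail of the Wallenius
    noncentral hypergeometric distribution with odds equal to the ratio of
    mean selection weights inside vs outside the term.  With constant weights
    this reduces to the central hypergeometric test.
    """
    de = de_flags.astype(bool)
    if de.all() or not de.any():
        raise ValueError("de_flags must contain both selected and unselected genes")
    if weights is None:
        if lengths is None:
            raise ValueError("provide weights or lengths")
        weights = length_bias_weights(de, lengths)
    universe = list(de.index.astype(str))
    test_set = list(de.index[de.values].astype(str))
    by_term_u = annot.terms_in(universe)
    by_term_t = annot.terms_in(test_set)
    n_univ, n_test = len(universe), len(test_set)
    w = weights.astype(float)
    w.index = w.index.astype(str)
    rows = []
    for term in sorted(by_term_u):
        in_term = sorted(by_term_u[term])
        big_k = len(in_term)
        k = len(by_term_t.get(term, ()))
        w_in = float(w.loc[in_term].mean())
        out_genes = [g for g in universe if g not in by_term_u[term]]
        w_out = float(w.loc[out_genes].mean()) if out_genes else w_in
        odds = w_in / w_out if w_out > 0 else 1.0
        if big_k == n_univ:
            p = 1.0  # every gene carries the term; no enrichment is definable
        else:
            p = float(nchypergeom_wallenius.sf(k - 1, n_univ, big_k, n_test, odds))
        p = min(max(p, 0.0), 1.0)
        rows.append({"term": term, "k_test": k, "n_test": n_test,
                     "k_universe": big_k, "n_universe": n_univ,
                     "odds": odds, "p": p})
    table = pd.DataFrame(rows).set_index("term")
    table["fdr"] = multipletests(table["p"].values, method="fdr_bh")[1]
    table["significant"] = table["fdr"] < alpha
    return EnrichmentResult(table=table, alpha=alpha, method="wallenius")


def slim_rollup(result: EnrichmentResult, slim_map: dict[str, str]) -> pd.Series:
    """Count significant terms per slim category (unmapped terms -> 'other')."""
    counts: dict[str, int] = {}
    for term in result.significant_terms:
        cat = slim_map.get(term, "other")
        counts[cat] = counts.get(cat, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()
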