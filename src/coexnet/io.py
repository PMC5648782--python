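"""TSV/JSON/Newick readers and writers for pipeline artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .modules import Dendrogram
from .preprocess import CountMatrix


def write_counts(cm: CountMatrix, counts_path, lengths_path=None, meta_path=None) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    if lengths_path is not None:
        cm.gene_length_bp.rename("length_bp").to_csv(lengths_path, sep="\t")
    if meta_path is not None:
        cm.sample_meta.to_csv(meta_path, sep="\t")


def read_counts(counts_path, lengths_path, meta_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(counts=counts, gene_length_bp=lengths, sample_meta=meta)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")


def dendrogram_to_newick(dend: Dendrogram, support: pd.DataFrame | None = None) -> str:
    """Serialize a dendrogram as Newick with branch lengths from merge heights.

    If a support table is given (columns ``leaves``, ``bp``, ``au``, with
    ``leaves`` a comma-joined sorted leaf-name list), internal nodes carry a
    ``[&au=..,bp=..]`` comment tag.
    """
    z = dend.linkage
    n = dend.n_leaves
    names = [str(x) for x in dend.labels]
    sup = {}
    if support is not None:
        for _, row in support.iterrows():
            sup[row["leaves"]] = (row.get("au"), row.get("bp"))

    heights = [0.0] * n + [float(h) for h in z[:, 2]]
    leafsets: list[frozenset] = [frozenset([i]) for i in range(n)]
    for a, b, *_ in z:
        leafsets.append(leafsets[int(a)] | leafsets[int(b)])

    def render(node: int, parent_h: float) -> str:
        bl = max(parent_h - heights[node], 0.0)
        if node < n:
            return f"{names[node]}:{bl:.6g}"
        a, b = int(z[node - n, 0]), int(z[node - n, 1])
        inner = f"({render(a, heights[node])},{render(b, heights[node])})"
        key = ",".join(sorted(names[i] for i in leafsets[node]))
        tag = ""
        if key in sup:
            au, bp = sup[key]
            tag = f"[&au={au:.4g},bp={bp:.4g}]"
        return f"{inner}{tag}:{bl:.6g}"

    root = n + len(z) - 1
    return render(root, heights[root]) + ";"
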