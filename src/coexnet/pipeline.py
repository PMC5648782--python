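"""End-to-end orchestration of the co-expression analysis stages."""

from __future__ import annotations


import logging
import time
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .enrich import AnnotationMap, overrepresentation
from .modules import (
    ModuleSet, cut_dynamic, hclust_average, hub_genes, kme, merge_modules,
    module_trait_cor,
)
from .network import (
    adjacency_signed_hybrid, bicor, pick_soft_threshold, recommended_power, tom,
)
from .partition import scan
from .preprocess import (
    CountMatrix, filter_abundance, filter_variance, tmm_normalize,
)
from .samples import classical_mds, multiscale_bootstrap, sample_cor_dist
from .simulate import SimConfig, simulate_counts, simulate_traits

log = logging.getLogger("coexnet")


@dataclass
class PipelineConfig:
    """Resolved parameters of a full pipeline run.

    Input paths may be omitted when ``simulate`` is true, in which case the
    synthetic generator provides counts and traits.  Unknown keys in a config
    file are rejected.
    """

    counts_path: str | None = None
    lengths_path: str | None = None
    meta_path: str | None = None
    traits_path: str | None = None
    annotations_path: str | None = None
    simulate: bool = True
    sim: dict = field(default_factory=dict)

    min_count: int = 5
    abundance_mode: str = "cpm"
    var_factor: float = 2.0
    var_stat: str = "mean"
    trim_m: float = 0.30
    trim_a: float = 0.05

    powers: tuple = tuple(range(1, 31))
    target_r2: float = 0.85
    power: int | None = None  # fixed power; None = auto-select
    max_p_outliers: float = 0.1

    min_module_size: int = 50
    deep_split: int = 2
    me_diss_threshold: float = 0.1
    kme_min: float = 0.9
    kme_p_max: float = 1e-6

    scan_alpha: float = 0.01
    scan_family: str = "partitions_modules"

    boot_b: int = 1000
    boot_scales: tuple = tuple(np.round(np.linspace(0.5, 1.4, 10), 10))
    enrich_alpha: float = 0.05

    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("powers", "boot_scales"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["powers"] = list(self.powers)
        d["boot_scales"] = [float(s) for s in self.boot_scales]
        return d


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage and write artifacts plus a summary under out_dir.

    Stages: (simulate) -> filter -> TMM -> network -> modules -> traits ->
    partition scan -> bootstrap clustering + MDS -> (enrichment).  Identical
    config and seed give an identical summary.  A stage failure raises with
    the stage name prefixed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cio.write_json(config.to_dict(), out / "config.json")
    summary: dict = {"seed": config.seed}
    t0 = time.time()

    def stage(name):
        log.info("stage=%s seed=%d elapsed=%.1fs", name, config.seed, time.time() - t0)

    try:
        stage("input")
        truth = None
        if config.simulate:
            sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
            cm, truth = simulate_counts(sim_cfg)
            traits = simulate_traits(sim_cfg, truth)
            cio.write_counts(cm, out / "counts.tsv", out / "lengths.tsv", out / "samples.tsv")
            traits.to_csv(out / "traits.tsv", sep="\t")
            cio.write_json(truth.to_dict(), out / "truth.json")
        else:
            cm = cio.read_counts(config.counts_path, config.lengths_path, config.meta_path)
            traits = pd.read_csv(config.traits_path, sep="\t", index_col=0)
        summary["n_genes_input"] = int(cm.counts.shape[0])
        summary["n_samples"] = int(cm.counts.shape[1])
    except Exception as e:
        raise RuntimeError(f"stage 'input' failed: {e}") from e

    try:
        stage("preprocess")
        cm_f = filter_abundance(cm, config.min_count, mode=config.abundance_mode)
        expr_all = tmm_normalize(cm_f, trim_M=config.trim_m, trim_A=config.trim_a)
        values, removed = filter_variance(
            expr_all.values, factor=config.var_factor, stat=config.var_stat
        )
        filter_log = expr_all.filter_log + [{
            "step": "variance",
            "rule": f"gene variance >= {config.var_factor} x {config.var_stat}",
            "removed": int(len(removed)), "kept": int(values.shape[0]),
        }]
        cio.write_matrix(values, out / "expr.tsv")
        cio.write_json(filter_log, out / "filter_log.json")
        summary["n_genes_abundance"] = int(cm_f.counts.shape[0])
        summary["n_genes_filtered"] = int(values.shape[0])
        summary["tmm_factors"] = {
            str(k): round(float(v), 6) for k, v in expr_all.tmm_factors.items()
        }
    except Exception as e:
        raise RuntimeError(f"stage 'preprocess' failed: {e}") from e

    try:
        stage("network")
        cor = bicor(values, max_p_outliers=config.max_p_outliers)
        if config.power is None:
            fit = pick_soft_threshold(cor, powers=config.powers, target_r2=config.target_r2)
            fit.table.to_csv(out / "power_fit.tsv", sep="\t", index=False)
            if fit.chosen_power is None:
                row = None
                summary["scale_free_r2"] = None
            else:
                row = fit.table[fit.table["power"] == fit.chosen_power].iloc[0]
                summary["scale_free_r2"] = round(float(row["signed_r2"]), 4)
            if row is not None and row["signed_r2"] >= config.target_r2:
                power = fit.chosen_power
                summary["power_source"] = "scale_free_fit"
            else:
                # no candidate reaches the target: use the sample-size default
                # rather than the best of a failed fit
                power = recommended_power(values.shape[1])
                summary["power_source"] = "sample_size_default"
        else:
            power = config.power
            summary["power_source"] = "fixed"
        net = tom(adjacency_signed_hybrid(cor, power))
        summary["power"] = int(power)
    except Exception as e:
        raise RuntimeError(f"stage 'network' failed: {e}") from e

    try:
        stage("modules")
        dend = hclust_average(net.diss_tom)
        labels0 = cut_dynamic(dend, config.min_module_size, config.deep_split)
        summary["n_modules_premerge"] = int(labels0[labels0 != 0].nunique())
        if summary["n_modules_premerge"] == 0:
            mods = ModuleSet(
                labels=labels0,
                eigengenes=pd.DataFrame(columns=values.columns),
                variance_explained=pd.Series(dtype=float),
            )
        else:
            mods = merge_modules(values, labels0, config.me_diss_threshold)
            mods.kme, mods.kme_p = kme(values, mods.eigengenes)
            mods.kme.to_csv(out / "kme.tsv", sep="\t")
            mods.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
        mods.labels.to_csv(out / "modules.tsv", sep="\t")
        summary["n_modules_merged"] = int(len(mods.eigengenes))
        summary["n_unassigned"] = int((mods.labels == 0).sum())
        if mods.kme is not None:
            hubs = hub_genes(mods.kme, mods.kme_p, mods.labels,
                             config.kme_min, config.kme_p_max)
            summary["n_hub_genes"] = int(sum(len(v) for v in hubs.values()))
            cio.write_json({str(k): v for k, v in hubs.items()}, out / "hub_genes.json")
    except Exception as e:
        raise RuntimeError(f"stage 'modules' failed: {e}") from e

    scan_res = None
    if len(mods.eigengenes):
        try:
            stage("traits")
            numeric = traits.select_dtypes("number")
            mt = module_trait_cor(mods.eigengenes, numeric)
            mt_table = pd.concat(
                {"r": mt.r, "p": mt.p, "fdr": mt.fdr}, axis=1
            )
            mt_table.to_csv(out / "module_trait.tsv", sep="\t")
            summary["n_modules_trait_significant"] = int(
                (mt.fdr < 0.05).any(axis=1).sum()
            )
        except Exception as e:
            raise RuntimeError(f"stage 'traits' failed: {e}") from e

        try:
            stage("scan")
            scan_res = scan(mods.eigengenes, alpha=config.scan_alpha,
                            family=config.scan_family)
            scan_res.table.to_csv(out / "partition_scan.tsv", sep="\t")
            summary["n_partitions"] = int(scan_res.n_partitions)
            summary["n_modules_partition_flagged"] = int(scan_res.table["flagged"].sum())
        except Exception as e:
            raise RuntimeError(f"stage 'scan' failed: {e}") from e

    try:
        stage("samples")
        support = multiscale_bootstrap(
            values, scales=tuple(config.boot_scales), n_boot=config.boot_b,
            seed=config.seed,
        )
        support.table.to_csv(out / "cluster_support.tsv", sep="\t", index=False)
        (out / "samples.nwk").write_text(
            cio.dendrogram_to_newick(support.dendrogram, support.table) + "\n"
        )
        coords, eigvals = classical_mds(sample_cor_dist(values), k=2)
        coords.to_csv(out / "mds.tsv", sep="\t")
        summary["min_top_cluster_au"] = round(
            float(_top_cluster_au(support)), 4
        )
    except Exception as e:
        raise RuntimeError(f"stage 'samples' failed: {e}") from e

    if config.annotations_path:
        try:
            stage("enrich")
            annot = AnnotationMap.from_tsv(config.annotations_path)
            universe = list(values.index)
            test = list(mods.labels.index[mods.labels == 1]) or universe[:1]
            res = overrepresentation(test, universe, annot, alpha=config.enrich_alpha)
            res.table.to_csv(out / "enrichment.tsv", sep="\t")
            summary["n_terms_significant"] = int(res.table["significant"].sum())
        except Exception as e:
            raise RuntimeError(f"stage 'enrich' failed: {e}") from e

    if truth is not None and len(mods.eigengenes):
        from sklearn.metrics import adjusted_rand_score

        summary["recovery_ari"] = round(float(adjusted_rand_score(
            truth.labels.reindex(mods.labels.index).values, mods.labels.values
        )), 4)

    cio.write_json(summary, out / "summary.json")
    return summary


def _top_cluster_au(support) -> float:
    """AU of the two children of the root cluster (the top-level split)."""
    z = support.dendrogram.linkage
    n = support.dendrogram.n_leaves
    names = [str(x) for x in support.dendrogram.labels]
    sets: list[frozenset] = [frozenset([i]) for i in range(n)]
    for a, b, *_ in z:
        sets.append(sets[int(a)] | sets[int(b)])
    root_children = [int(z[-1, 0]), int(z[-1, 1])]
    aus = []
    for c in root_children:
        if c < n:
            continue  # singleton child: no cluster to support
        key = ",".join(sorted(names[i] for i in sets[c]))
        row = support.table[support.table["leaves"] == key]
        if len(row):
            aus.append(float(row["au"].iloc[0]))
    return min(aus) if aus else float("nan")
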