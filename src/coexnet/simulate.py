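"""Synthetic RNA-seq count data with planted co-expression structure.

Generates a genes x samples count matrix that emulates a short, stage-resolved
developmental time course sequenced one embryo per library: a handful of
planted co-expression modules whose eigengene trajectories follow smooth
temporal shapes (early-high, late-high, mid-switch), an optional module driven
by a hidden binary covariate (a sex-like factor that is not recorded in the
sample metadata), negative-binomial sampling noise, and variable library
sizes.  The planted truth is returned alongside the counts so that every
downstream stage of the pipeline (filtering, network construction, module
detection, trait correlation, partition scanning) can be validated against a
known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

TRAJECTORY_KINDS = ("early_high", "late_high", "mid_switch", "covariate_linked", "flat")

#: 15 libraries over 9 days: days 1-6 sequenced in duplicate (individuals a/b),
#: days 7-9 as single embryos.
DEFAULT_DAYS = (1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 6, 6, 7, 8, 9)


@dataclass
class SimConfig:
    """Parameters of the synthetic count generator.

    Attributes
    ----------
    n_genes:
        Total number of genes, planted modules included.
    n_samples:
        Number of libraries (one embryo each).
    stage_of_sample:
        Integer day label per sample.  Defaults to the 15-sample layout with
        days 1-6 duplicated and days 7-9 single.
    module_sizes:
        Number of member genes of each planted module.  Genes not in any
        module are background (flat trajectory, label 0).
    trajectories:
        One trajectory kind per module, drawn from
        ``early_high | late_high | mid_switch | covariate_linked | flat``.
    loading_mean, loading_sd:
        Mean and spread (log2 units) of the per-gene loading that multiplies
        the standardized module trajectory in the log-mean model
        ``log2 mean = baseline + loading * trajectory``.
    covariate_effect:
        Loading mean used for a ``covariate_linked`` module (binary offset on
        the log2 mean between the two hidden groups).
    nb_dispersion:
        Negative-binomial dispersion alpha with variance ``mu + alpha * mu**2``.
    libsize_range:
        Uniform range of expected library sizes (total counts per sample).
    length_range_bp:
        Uniform range of gene lengths in bp.
    seed:
        Master seed; all randomness flows from it through named
        ``numpy.random.SeedSequence`` children (lengths, baselines, loadings,
        covariate, libsizes, counts), so identical seeds give bit-identical
        output.
    """

    n_genes: int = 2300
    n_samples: int = 15
    stage_of_sample: tuple[int, ...] = DEFAULT_DAYS
    module_sizes: tuple[int, ...] = (100, 100, 100)
    trajectories: tuple[str, ...] = ("early_high", "mid_switch", "late_high")
    loading_mean: float = 2.0
    loading_sd: float = 0.35
    covariate_effect: float = 2.0
    baseline_range: tuple[float, float] = (3.0, 9.0)
    nb_dispersion: float = 0.08
    libsize_range: tuple[float, float] = (8e5, 1.2e6)
    length_range_bp: tuple[int, int] = (300, 5000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_samples <= 0:
            raise ValueError("n_genes and n_samples must be positive")
        if len(self.stage_of_sample) != self.n_samples:
            raise ValueError(
                f"stage_of_sample has {len(self.stage_of_sample)} entries "
                f"for {self.n_samples} samples"
            )
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum(module_sizes) exceeds n_genes")
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if len(self.trajectories) != len(self.module_sizes):
            raise ValueError("need one trajectory kind per module")
        for t in self.trajectories:
            if t not in TRAJECTORY_KINDS:
                raise ValueError(f"unknown trajectory kind {t!r}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not (0 < self.libsize_range[0] <= self.libsize_range[1]):
            raise ValueError("libsize_range must be positive and ordered")
        if not (0 < self.length_range_bp[0] <= self.length_range_bp[1]):
            raise ValueError("length_range_bp must be positive and ordered")
        if self.loading_sd <= 0:
            raise ValueError("loading_sd must be positive")


@dataclass
class PlantedTruth:
    """Ground truth of a simulation: module labels, trajectories, covariate."""

    labels: pd.Series  # gene -> module id, 0 = background
    trajectories: pd.DataFrame  # modules x samples, zero mean / unit variance
    covariate: np.ndarray | None  # binary per sample, None if no covariate module

    def to_dict(self) -> dict:
        return {
            "labels": self.labels.to_dict(),
            "trajectories": {
                str(m): list(map(float, row))
                for m, row in self.trajectories.iterrows()
            },
            "covariate": None if self.covariate is None else [int(c) for c in self.covariate],
        }


def _logistic_ramp(day: np.ndarray, center: float, scale: float, rising: bool) -> np.ndarray:
    z = (day - center) / scale
    y = 1.0 / (1.0 + np.exp(-z))
    return y if rising else 1.0 - y


def _standardize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("trajectory is constant; cannot standardize")
    return (v - v.mean()) / sd


def trajectory_profile(kind: str, days: np.ndarray, covariate: np.ndarray | None = None) -> np.ndarray:
    """Zero-mean, unit-variance module trajectory over samples.

    early_high: high early, down-regulated after mid-development, with a mild
    late recovery; mid_switch is its antagonist (low early, up after mid,
    dipping again at the end); late_high rises monotonically from mid
    development and peaks at the final stages; covariate_linked follows the
    hidden binary covariate; flat is a constant (only usable for background,
    never standardized).
    """
    days = np.asarray(days, dtype=float)
    lo, hi = days.min(), days.max()
    mid = 0.5 * (lo + hi)
    span = max(hi - lo, 1.0)
    if kind == "early_high":
        fall = _logistic_ramp(days, mid, span / 5, rising=False)
        late = _logistic_ramp(days, lo + 0.9 * span, span / 18, rising=True)
        return _standardize(fall + 0.35 * late)
    if kind == "late_high":
        return _standardize(_logistic_ramp(days, lo + 0.7375 * span, span / 5, rising=True))
    if kind == "mid_switch":
        rise = _logistic_ramp(days, lo + 0.525 * span, span / 6, rising=True)
        dip = _logistic_ramp(days, lo + 0.825 * span, span / 10, rising=True)
        return _standardize(rise - 1.2 * dip)
    if kind == "covariate_linked":
        if covariate is None:
            raise ValueError("covariate_linked trajectory requires a covariate")
        return _standardize(covariate.astype(float))
    if kind == "flat":
        return np.zeros_like(days)
    raise ValueError(f"unknown trajectory kind {kind!r}")


def simulate_counts(config: SimConfig) -> tuple["CountMatrix", PlantedTruth]:
    """Draw a count matrix with planted modules and return it with its truth.

    Module genes follow ``log2 mean = baseline + loading * trajectory(sample)``;
    expected counts are rescaled per sample so totals match the drawn library
    size, then negative-binomial noise is applied.
    """
    from .preprocess import CountMatrix

    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss = dict(zip(
        ["lengths", "baselines", "loadings", "covariate", "libsizes", "counts"],
        root.spawn(6),
    ))

    g, n = config.n_genes, config.n_samples
    days = np.asarray(config.stage_of_sample)
    gene_ids = pd.Index([f"g{i:05d}" for i in range(g)], name="gene")
    sample_ids = _sample_ids(days)

    rng_len = np.random.default_rng(ss["lengths"])
    lengths = rng_len.integers(config.length_range_bp[0], config.length_range_bp[1] + 1, size=g)

    rng_base = np.random.default_rng(ss["baselines"])
    baseline = rng_base.uniform(*config.baseline_range, size=g)

    covariate = None
    if "covariate_linked" in config.trajectories:
        if config.trajectories.count("covariate_linked") > 1:
            raise ValueError("at most one covariate_linked module")
        rng_cov = np.random.default_rng(ss["covariate"])
        # balanced-as-possible hidden split, shuffled across samples
        covariate = np.zeros(n, dtype=int)
        covariate[: n // 2] = 1
        rng_cov.shuffle(covariate)

    labels = np.zeros(g, dtype=int)
    traj_rows = []
    start = 0
    rng_load = np.random.default_rng(ss["loadings"])
    log2_mu = np.tile(baseline[:, None], (1, n))
    for m, (size, kind) in enumerate(zip(config.module_sizes, config.trajectories), start=1):
        idx = slice(start, start + size)
        labels[idx] = m
        traj = trajectory_profile(kind, days, covariate)
        traj_rows.append(traj)
        mean = config.covariate_effect if kind == "covariate_linked" else config.loading_mean
        loading = rng_load.normal(mean, config.loading_sd, size=size)
        if kind != "flat":
            log2_mu[idx, :] = baseline[idx, None] + loading[:, None] * traj[None, :]
        start += size

    rng_lib = np.random.default_rng(ss["libsizes"])
    libsizes = rng_lib.uniform(*config.libsize_range, size=n)

    rel = np.exp2(log2_mu)
    mu = rel / rel.sum(axis=0, keepdims=True) * libsizes[None, :]

    rng_counts = np.random.default_rng(ss["counts"])
    alpha = config.nb_dispersion
    if alpha < 1e-8:
        counts = rng_counts.poisson(mu)
    else:
        size_param = 1.0 / alpha
        p = size_param / (size_param + mu)
        counts = rng_counts.negative_binomial(size_param, p)

    meta = _sample_meta(days)
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        gene_length_bp=pd.Series(lengths, index=gene_ids, name="length_bp"),
        sample_meta=meta,
    )
    truth = PlantedTruth(
        labels=pd.Series(labels, index=gene_ids, name="module"),
        trajectories=pd.DataFrame(
            traj_rows,
            index=pd.RangeIndex(1, len(traj_rows) + 1, name="module"),
            columns=sample_ids,
        ),
        covariate=covariate,
    )
    return cm, truth


def _sample_ids(days: np.ndarray) -> pd.Index:
    ids, seen = [], {}
    for d in days:
        k = seen.get(d, 0)
        seen[d] = k + 1
        ids.append(f"d{d}{'ab'[k] if list(days).count(d) > 1 else 'a'}")
    return pd.Index(ids, name="sample")


def _sample_meta(days: np.ndarray) -> pd.DataFrame:
    seen: dict[int, int] = {}
    individual = []
    for d in days:
        k = seen.get(d, 0)
        seen[d] = k + 1
        individual.append("ab"[k] if k < 2 else str(k))
    return pd.DataFrame(
        {"day": days, "individual": individual},
        index=_sample_ids(days),
    )


def simulate_traits(
    config: SimConfig,
    truth: PlantedTruth,
    clade_boundary: int = 5,
    withhold_covariate: bool = True,
) -> pd.DataFrame:
    """Sample trait table: day, clade (day > boundary), individual replicate.

    The hidden covariate is withheld by default, mirroring a study where sex
    was never recorded; set ``withhold_covariate=False`` to expose it (e.g.
    to validate the partition scan).
    """
    config.validate()
    days = np.asarray(config.stage_of_sample)
    meta = _sample_meta(days)
    traits = pd.DataFrame(index=meta.index)
    traits["day"] = meta["day"].astype(float)
    traits["clade"] = (meta["day"] > clade_boundary).astype(float)
    traits["individual"] = (meta["individual"] == "b").astype(float)
    if not withhold_covariate:
        if truth.covariate is None:
            raise ValueError("no covariate was planted in this simulation")
        traits["covariate"] = truth.covariate.astype(float)
    return traits


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
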