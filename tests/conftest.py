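import numpy as np
import pandas as pd
import pytest

from coexnet import SimConfig, simulate_counts, simulate_traits


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic study: 3 planted modules of 100 genes + background."""
    cfg = SimConfig(seed=11)
    cm, truth = simulate_counts(cfg)
    traits = simulate_traits(cfg, truth)
    return cfg, cm, truth, traits


@pytest.fixture(scope="session")
def small_sim():
    """Small, fast simulation for unit tests."""
    cfg = SimConfig(seed=7, n_genes=400, module_sizes=(60, 60),
                    trajectories=("early_high", "late_high"))
    cm, truth = simulate_counts(cfg)
    return cfg, cm, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_count_matrix(counts, days=None):
    """Build a CountMatrix around a plain integer array."""
    from coexnet import CountMatrix

    counts = np.asarray(counts)
    g, n = counts.shape
    genes = pd.Index([f"g{i}" for i in range(g)])
    samples = pd.Index([f"s{j}" for j in range(n)])
    days = list(days) if days is not None else list(range(1, n + 1))
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        gene_length_bp=pd.Series(1000, index=genes),
        sample_meta=pd.DataFrame(
            {"day": days, "individual": ["a"] * n}, index=samples
        ),
    )
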