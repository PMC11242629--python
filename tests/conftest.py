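import numpy as np
import pandas as pd
import pytest

from glmqlmas import (
    RunConfig,
    SimulationConfig,
    de_analysis,
    drop_unexpressed,
    generate_cohort,
    tmm_normalize,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Planted-effect cohort small enough for per-test reuse."""
    cfg = SimulationConfig(
        n_genes=400,
        n_coding=400,
        group_sizes=(20, 14),
        de_fraction=0.1,
        de_log2fc_magnitudes=(2.0,),
        dispersion=0.1,
        seed=42,
    )
    counts, samples, genes, truth = generate_cohort(cfg)
    counts, _ = drop_unexpressed(counts)
    return counts, samples, genes, truth


@pytest.fixture(scope="session")
def small_de_table(small_cohort):
    counts, samples, _, truth = small_cohort
    factors = tmm_normalize(counts)
    de = de_analysis(counts, samples, factors, RunConfig())
    return de, truth


def random_de_table(rng: np.random.Generator, n: int = 100) -> pd.DataFrame:
    """Random but well-formed DE table for ranking oracles."""
    lfc = rng.normal(0, 2, n)
    p = rng.uniform(1e-12, 1, n)
    return pd.DataFrame(
        {
            "gene": [f"g{i:04d}" for i in range(n)],
            "log2FC": lfc,
            "avg_logCPM": rng.uniform(0, 10, n),
            "F": rng.chisquare(1, n),
            "p": p,
            "p_BH": np.clip(p * rng.uniform(1, 2, n), 1e-12, 1),
            "p_bonf": np.clip(p * n, 1e-12, 1),
        }
    )
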