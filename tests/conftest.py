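import numpy as np
import pandas as pd
import pytest

from heterosim import SimulationConfig, run_contrasts, simulate_counts
from heterosim.io import CountMatrix


@pytest.fixture(scope="session")
def default_world():
    """Moderate stochastic world under the study-shaped default mix."""
    cfg = SimulationConfig(n_genes=4000, n_mirnas=250, seed=11)
    genes, mirnas, truth = simulate_counts(cfg)
    return cfg, genes, mirnas, truth


@pytest.fixture(scope="session")
def default_gene_calls(default_world):
    _, genes, _, _ = default_world
    return run_contrasts(genes)


@pytest.fixture(scope="session")
def injection_world():
    """Deterministic mean-injection world spanning all 13 truth labels."""
    cfg = SimulationConfig(n_genes=2000, n_mirnas=300, mean_injection=True, seed=7)
    genes, mirnas, truth = simulate_counts(cfg)
    return cfg, genes, mirnas, truth


def small_count_matrix(counts: np.ndarray, stocks: list[str],
                       lengths: np.ndarray | None = None,
                       feature_type: str = "gene") -> CountMatrix:
    """Hand-built matrix helper for unit tests."""
    counts = np.asarray(counts)
    samples = []
    seen: dict[str, int] = {}
    for s in stocks:
        seen[s] = seen.get(s, 0) + 1
        samples.append(f"{s}{seen[s]}")
    df = pd.DataFrame(counts, columns=samples,
                      index=[f"f{i}" for i in range(counts.shape[0])])
    design = pd.DataFrame(
        {"stock": stocks, "replicate": [int(s[-1]) for s in samples]}, index=df.columns)
    lens = None
    if lengths is not None:
        lens = pd.Series(lengths, index=df.index, name="length_nt")
    return CountMatrix(df, design, lengths=lens, feature_type=feature_type)
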