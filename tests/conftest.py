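import numpy as np
import pandas as pd
import pytest

from poolsel import SimulationConfig, filter_pipeline, generate_experiment


@pytest.fixture(scope="session")
def small_config():
    """A fast scenario preserving the study's shape (3+3 replicates, two
    sampled generations) at reduced size."""
    return SimulationConfig(
        n_lines=27, haploids_per_line=4, arms=(("2L", 400_000),),
        n_loci=250, ne=150, depth_mean=60.0, pool_individuals=80,
        free_recombination=True, seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return generate_experiment(small_config)


@pytest.fixture(scope="session")
def small_filtered(small_experiment):
    table, design, truth, founders = small_experiment
    bial, report = filter_pipeline(table, design)
    return bial, report, design


@pytest.fixture(scope="session")
def toy_genes():
    return pd.DataFrame({
        "gene": ["gA", "gB", "gC"],
        "arm": ["2L", "2L", "2L"],
        "start": [10_000, 50_000, 52_000],
        "end": [20_000, 60_000, 58_000],
    })


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
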