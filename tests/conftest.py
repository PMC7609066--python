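import numpy as np
import pandas as pd
import pytest

from scvasc.preprocess import lognormalize, qc_filter
from scvasc.simulate import SimulationConfig, simulate_cells


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_clusters=3,
        cells_per_cluster_wt=[120, 120, 60],
        expansion_factor_ko=[1.0, 1.0, 4.0],
        n_genes=200,
        baseline_mean=0.5,
        markers_per_cluster=8,
        marker_fold=8.0,
        de_genes_ko={0: [("G0100", 1.2), ("G0101", -1.2)]},
        mito_gene_count=8,
        mito_fraction_mean=0.02,
        mito_fraction_sd=0.005,
        positivity_profiles={
            "G0190": {0: {"wt": 0.2, "ko": 0.6}, 1: {"wt": 0.2, "ko": 0.2},
                      2: {"wt": 0.2, "ko": 0.2}},
        },
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_cells(small_config)


@pytest.fixture(scope="session")
def small_norm(small_sim):
    counts, truth = small_sim
    filtered, _ = qc_filter(counts)
    norm = lognormalize(filtered)
    clusters = truth.cells.loc[norm.cells, "cluster"]
    return norm, clusters, truth
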