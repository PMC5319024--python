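import numpy as np
import pandas as pd
import pytest

import tilscore as ts

FOUR_GENE_PANEL = ["GENE1", "GENE2", "GENE3", "GENE4"]


@pytest.fixture
def rng():
    return np.random.default_rng(20170221)


@pytest.fixture(scope="session")
def four_gene():
    """The canned four-gene QC walkthrough dataset (default seed)."""
    return ts.four_gene_scenario()


@pytest.fixture(scope="session")
def four_gene_similarity(four_gene):
    return ts.similarity_matrix(four_gene.expression, FOUR_GENE_PANEL)


@pytest.fixture
def counts_matrix():
    """Tiny raw-count matrix: 3 genes x 2 samples."""
    df = pd.DataFrame(
        {"s1": [10.0, 0.0, 100.0], "s2": [20.0, 5.0, 50.0]},
        index=["CD19", "CD3D", "PTPRC"],
    )
    return ts.ExpressionMatrix(df, ts.Scale.raw_counts)


@pytest.fixture(scope="session")
def simulated_two_cell():
    """Two independent cell types with pure markers plus a noise gene."""
    cfg = ts.SimulationConfig(
        n_samples=500,
        cell_types=[
            ts.CellTypeSpec("Alpha", log2_mean=5.0, log2_sd=1.0),
            ts.CellTypeSpec("Beta", log2_mean=4.0, log2_sd=1.0),
        ],
        genes=[
            ts.GeneSpec("A1", {"Alpha": 2.0}, noise_sd=0.1),
            ts.GeneSpec("A2", {"Alpha": 4.0}, noise_sd=0.1),
            ts.GeneSpec("A3", {"Alpha": 1.0}, noise_sd=0.1),
            ts.GeneSpec("B1", {"Beta": 2.0}, noise_sd=0.1),
            ts.GeneSpec("B2", {"Beta": 1.0}, noise_sd=0.1),
            ts.GeneSpec("JUNK", {}, noise_sd=1.0, baseline_log2=6.0),
        ],
        infiltrate_loading=0.0,
        seed=4242,
    )
    return ts.simulate(cfg)
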