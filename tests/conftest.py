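"""Shared fixtures: toy alignments and session-scoped simulated datasets."""

import numpy as np
import pytest

from divergc import CodonAlignment, SimulationConfig, simulate_dataset
from divergc.spectra import SpeciesTree

# fixed study-condition seeds for the simulated datasets used across tests
DATASET_SEED = 11
LAMBDA_SEEDS = {1.0: 21, 2.0: 22, 5.0: 23}


@pytest.fixture(scope="session")
def default_dataset():
    """300-gene dataset at default conditions (10% islands, lambda = 5)."""
    return simulate_dataset(SimulationConfig(n_genes=300, seed=DATASET_SEED))


@pytest.fixture(scope="session")
def small_dataset():
    """40-gene dataset for cheap structural tests."""
    return simulate_dataset(SimulationConfig(n_genes=40, seed=3))


@pytest.fixture(scope="session")
def lambda_datasets():
    """150-gene datasets across gBGC strengths 1, 2 and 5."""
    return {
        lam: simulate_dataset(
            SimulationConfig(n_genes=150, gbgc_lambda=lam, seed=seed)
        )
        for lam, seed in LAMBDA_SEEDS.items()
    }


def make_alignment(gene_id="toy", taxa=None, rows=None):
    taxa = taxa or ["human", "guinea_pig", "squirrel", "mouse", "rat", "sand_rat"]
    if rows is None:
        rows = ["ATGGCT" * 3] * len(taxa)
    return CodonAlignment(gene_id=gene_id, taxa=list(taxa), rows=list(rows))


@pytest.fixture
def toy_alignment():
    """Six taxa, six codon columns, fully identical (all columns conserved)."""
    return make_alignment(rows=["ATGGCTAAACCTGGATCT"] * 6)


@pytest.fixture
def star_tree():
    return SpeciesTree.from_newick(
        "((A:0.10,B:0.10)n1:0.05,(C:0.10,focal:0.10)n2:0.05)root;", is_path=False
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
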