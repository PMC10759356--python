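import numpy as np
import pandas as pd
import pytest

from pitscape.datatypes import CountMatrix, NormalizedMatrix, annotations_to_frame
from pitscape.qc import lognormalize
from pitscape.simulate import generate_sc_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A modest clustered dataset with planted structure, shared across tests."""
    counts, annotations, truth = generate_sc_dataset(
        n_genes=600, n_cells=900, seed=101, aggressive_fraction=0.05
    )
    return counts, annotations, truth


@pytest.fixture(scope="session")
def small_normalized(small_dataset):
    counts, annotations, truth = small_dataset
    return lognormalize(counts), annotations_to_frame(annotations), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_normalized(values, gene_ids=None, cell_ids=None) -> NormalizedMatrix:
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    cell_ids = cell_ids or [f"c{j}" for j in range(values.shape[1])]
    return NormalizedMatrix(values, gene_ids, cell_ids)


def make_counts(values, gene_ids=None, cell_ids=None) -> CountMatrix:
    values = np.asarray(values)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    cell_ids = cell_ids or [f"c{j}" for j in range(values.shape[1])]
    return CountMatrix(values, gene_ids, cell_ids)
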