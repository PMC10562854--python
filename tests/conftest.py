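"""Shared fixtures: toy dataset builder, the default synthetic atlas, and one
trained reference model (session-scoped; training is the expensive step)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import settings

from crossatlas import (
    CellDataset,
    SyntheticConfig,
    TrainConfig,
    simulate_atlas,
    train_classifier,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def build_dataset(
    counts,
    labels=None,
    condition=None,
    donor=None,
    dataset="DS1",
    biotype=None,
    gene_ids=None,
    cell_ids=None,
) -> CellDataset:
    """Assemble a CellDataset from a dense count array and optional metadata."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    cell_ids = list(cell_ids) if cell_ids is not None else [f"c{i:04d}" for i in range(n_cells)]
    gene_ids = list(gene_ids) if gene_ids is not None else [f"g{j:04d}" for j in range(n_genes)]
    meta = pd.DataFrame(
        {
            "dataset": dataset,
            "donor": donor if donor is not None else "D1",
            "condition": condition if condition is not None else "healthy",
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    if labels is not None:
        meta["label"] = list(labels)
    gene_meta = pd.DataFrame(
        {"biotype": biotype if biotype is not None else "protein_coding"},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return CellDataset(sp.csr_matrix(counts), meta, gene_meta)


def separable_dataset(n_per_type=40, seed=0) -> CellDataset:
    """Two cell types with disjoint marker supports — linearly separable."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_type
    counts = rng.poisson(0.2, size=(n, 20))
    counts[:n_per_type, :5] += rng.poisson(20, size=(n_per_type, 5))
    counts[n_per_type:, 5:10] += rng.poisson(20, size=(n_per_type, 5))
    labels = ["TypeA"] * n_per_type + ["TypeB"] * n_per_type
    return build_dataset(counts, labels=labels)


@pytest.fixture(scope="session")
def default_atlas():
    """The default desk-scale synthetic atlas (3 datasets, 21 types)."""
    config = SyntheticConfig(seed=0)
    datasets, truth = simulate_atlas(config)
    return config, datasets, truth


@pytest.fixture(scope="session")
def ref_model(default_atlas):
    """Reference classifier trained on the first dataset of the default atlas."""
    _, datasets, _ = default_atlas
    return train_classifier(datasets[0], config=TrainConfig(seed=0))
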