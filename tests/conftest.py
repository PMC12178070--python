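"""Shared fixtures: offline embedding provider, simulated batches, toy ontology."""

from __future__ import annotations

import numpy as np
import pytest
import scanpy as sc

from scprior import synthetic
from scprior.similarity import HashingEmbeddingProvider


@pytest.fixture(scope="session")
def provider() -> HashingEmbeddingProvider:
    return HashingEmbeddingProvider()


def prep_lognorm(datasets):
    """Normalize + log1p each batch into the 'lognorm' layer (in place)."""
    for adata in datasets:
        sc.pp.normalize_total(adata, target_sum=1e4)
        sc.pp.log1p(adata)
        adata.layers["lognorm"] = adata.X.copy()
    return datasets


def simulate_prepped(n_batches=3, cells_per_batch=300, seed=0, n_types=6,
                     proportions=None, **cfg_kwargs):
    """Simulated batches with the lognorm layer ready for integration."""
    types = synthetic.default_cell_types(n_types, cfg_kwargs.get("n_genes", 300))
    if proportions is not None:
        types = [synthetic.CellTypeSpec(t.name, p, t.markers, t.fold_change)
                 for t, p in zip(types, proportions)]
    cfg = synthetic.SimConfig(n_batches=n_batches, cells_per_batch=cells_per_batch,
                              cell_types=types, seed=seed, **cfg_kwargs)
    return prep_lognorm(synthetic.generate_batches(cfg))


@pytest.fixture(scope="session")
def three_batches():
    """Three 300-cell batches, six shared types, default batch effect."""
    return simulate_prepped(n_batches=3, cells_per_batch=300, seed=42)


@pytest.fixture(scope="session")
def toy_ontology():
    """Depth-2 binary tree: root, 2 children, 4 grandchildren."""
    return synthetic.generate_ontology(depth=2, branching=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
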