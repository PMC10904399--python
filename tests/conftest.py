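"""Shared fixtures.  Heavy artifacts (trained pipeline run, benchmark grid)
are session-scoped so several tests can share one computation."""

from __future__ import annotations

import numpy as np
import pytest

import funcsig as fs


@pytest.fixture(scope="session")
def two_cluster_graph():
    """20 genes in two disjoint 10-gene edge families."""
    genes = [f"g{i:02d}" for i in range(20)]
    uni = fs.GeneUniverse(genes)
    edges = fs.size_weight_expression([
        fs.Hyperedge("c1a", set(genes[:10])),
        fs.Hyperedge("c1b", set(genes[:10])),
        fs.Hyperedge("c2a", set(genes[10:])),
        fs.Hyperedge("c2b", set(genes[10:])),
    ])
    return fs.FunctionalHypergraph(uni, edges, mode="expression")


@pytest.fixture(scope="session")
def cluster_embeddings():
    """Synthetic embedding matrix with planted clusters plus labels."""
    spec = fs.FixtureSpec(seed=5, n_genes=120, n_pathways=6,
                          embedding_dim=24, embedding_noise_sd=0.25)
    return fs.generate_cluster_embeddings(spec)


@pytest.fixture(scope="session")
def cotarget_fixture():
    return fs.generate_cotarget_fixture(fs.FixtureSpec(seed=202))


@pytest.fixture(scope="session")
def cotarget_run(cotarget_fixture):
    """One end-to-end co-target pipeline run shared across tests."""
    return fs.run_cotarget_pipeline(cotarget_fixture, seed=9)


@pytest.fixture(scope="session")
def benchmark_frame():
    """Scaled-down signature-similarity benchmark: 20 synthetic pathways,
    50 repetitions per cell, lambda in {5, 10, 15, 20}."""
    spec = fs.FixtureSpec(seed=11, n_genes=2000, n_pathways=20,
                          pathway_size_range=(50, 200))
    pathways = fs.generate_pathway_collection(spec)
    return fs.run_benchmark_grid(pathways, spec.genes(),
                                 lambda_values=(5, 10, 15, 20), n_reps=50,
                                 seed=3, embed_dim=256, embed_epochs=30)


def make_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
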