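"""Shared fixtures: synthetic datasets, a small trained model, random hypergraphs."""

from __future__ import annotations

import numpy as np
import pytest

from amhf.hypergraph import Hypergraph
from amhf.io import train_test_split
from amhf.model import tiny_classifier
from amhf.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """200 clean (noise-free) peptides over 4 motif classes."""
    cfg = SyntheticConfig(n_classes=4, n_samples=200, noise_rate=0.0, seed=42)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_model(small_dataset):
    """A briefly trained all-branch classifier plus its train/test split."""
    train, test = train_test_split(small_dataset, 0.8, seed=5)
    y = np.stack([r.labels for r in train])
    clf = tiny_classifier(epochs=3, random_state=5)
    clf.fit(train, y)
    return clf, train, test


def random_hypergraph(rng: np.random.Generator, max_nodes: int = 8, max_edges: int = 4):
    """A random valid hypergraph (every edge nonempty, every node covered).

    Returns (Hypergraph, dense H, dense per-incidence weight matrix W).
    """
    n_v = int(rng.integers(2, max_nodes + 1))
    n_e = int(rng.integers(1, max_edges + 1))
    H = np.zeros((n_e, n_v), dtype=np.int8)
    for e in range(n_e):
        size = int(rng.integers(1, n_v + 1))
        H[e, rng.choice(n_v, size=size, replace=False)] = 1
    for v in range(n_v):
        if H[:, v].sum() == 0:
            H[rng.integers(n_e), v] = 1
    edge_ids, node_ids = np.nonzero(H)
    weight = rng.uniform(0.2, 2.0, size=len(edge_ids))
    W = np.zeros((n_e, n_v))
    W[edge_ids, node_ids] = weight
    graph = Hypergraph(
        node_vocab=[f"km{i}" for i in range(n_v)],
        n_edges=n_e,
        edge_ids=edge_ids.astype(np.int64),
        node_ids=node_ids.astype(np.int64),
        tf=np.ones(len(edge_ids)),
        weight=weight,
        node_global=np.arange(n_v, dtype=np.int64),
        df=H.sum(axis=0).astype(float),
        idf=np.zeros(n_v),
        k=2,
    )
    return graph, H, W
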