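"""k-mer hypergraph construction and hypergraph attention (HyperGAT).

Peptides that share function often share short subsequences.  To expose
this many-to-many structure, every sequence is split into overlapping
k-mers (stride 1, default k = 5); each distinct k-mer is a node and each
sequence is a hyperedge joining all its k-mer nodes.  The binary incidence
structure H (|E| x |V|) is stored sparsely as (edge, node) pairs, each
carrying a tf-idf weight: the k-mer's occurrence count within the sequence
times ln(|E| / df), where df is the number of sequences containing the
k-mer — the "frequency and diversity" weighting of the subsequences.

HyperGAT alternates two attention-weighted aggregation stages:

* hyperedge update — for edge e with previous feature h_e, each member
  node v is scored s(v) = LeakyReLU(<W'_v h_v, W'_e h_e>) * w_ev, the
  scores are softmax-normalized within the edge (beta), and
  h'_e = ELU(sum_v beta_v W'_v h_v);
* node update — for node v, each incident edge e is scored
  s(e) = LeakyReLU(<W_v h_v, W_e h_e>), softmax-normalized over the node's
  edges (alpha), and h'_v = ELU(sum_e alpha_e W_e h_e).

Initial edge features are the plain mean of member node embeddings; the
edge update runs first in every layer (node updates consume edge
features).  The per-sequence branch feature is the sequence's edge feature
after a final edge update, linearly projected.

Training is transductive over the training-set hypergraph; unseen
sequences at inference attach to the frozen k-mer vocabulary (unknown
k-mers map to a reserved UNK node) with df/idf frozen from training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._tensor import Tensor, segment_softmax, segment_sum
from .io import PeptideRecord

__all__ = [
    "kmers",
    "Hypergraph",
    "build_hypergraph",
    "inference_hypergraph",
    "HyperGATParams",
    "edge_update",
    "node_update",
    "HyperGATBranch",
]


def kmers(sequence: str, k: int) -> list[str]:
    """Overlapping stride-1 k-mers, in order (len(sequence) - k + 1 of them)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(sequence):
        raise ValueError(f"k={k} exceeds sequence length {len(sequence)}")
    return [sequence[i : i + k] for i in range(len(sequence) - k + 1)]


@dataclass
class Hypergraph:
    """Sparse k-mer hypergraph.

    ``edge_ids`` / ``node_ids`` list the (hyperedge, local node) incidence
    pairs; ``node_global`` maps local node indices to the k-mer vocabulary
    (index ``len(node_vocab)`` is the UNK node).  ``weight`` carries the
    tf-idf incidence weights, ``tf`` the raw within-sequence counts.
    """

    node_vocab: list[str]
    n_edges: int
    edge_ids: np.ndarray
    node_ids: np.ndarray
    tf: np.ndarray
    weight: np.ndarray
    node_global: np.ndarray
    df: np.ndarray
    idf: np.ndarray
    k: int
    record_ids: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        """Number of (local) nodes actually present."""
        return len(self.node_global)

    def incidence_matrix(self) -> np.ndarray:
        """Dense binary |E| x |V local| incidence matrix H."""
        H = np.zeros((self.n_edges, self.n_nodes), dtype=np.int8)
        H[self.edge_ids, self.node_ids] = 1
        return H

    def validate(self) -> None:
        H = self.incidence_matrix()
        if (H.sum(axis=1) < 1).any():
            raise ValueError("every hyperedge must contain at least one node")
        if self.n_nodes and (H.sum(axis=0) < 1).any():
            raise ValueError("every node must belong to at least one hyperedge")


def _check_lengths(records: list[PeptideRecord], k: int) -> None:
    short = [r.id for r in records if len(r.sequence) < k]
    if short:
        raise ValueError(f"sequences shorter than k={k}: {short}")


def build_hypergraph(records: list[PeptideRecord], k: int = 5) -> Hypergraph:
    """Build the training hypergraph over all given sequences.

    Node vocabulary is in first-occurrence order; weights are
    tf * ln(|E| / df).
    """
    _check_lengths(records, k)
    vocab: dict[str, int] = {}
    edge_ids, node_ids, tfs = [], [], []
    for j, rec in enumerate(records):
        counts: dict[str, int] = {}
        for km in kmers(rec.sequence, k):
            counts[km] = counts.get(km, 0) + 1
        for km, c in counts.items():
            i = vocab.setdefault(km, len(vocab))
            edge_ids.append(j)
            node_ids.append(i)
            tfs.append(c)
    n_edges = len(records)
    n_vocab = len(vocab)
    edge_ids = np.asarray(edge_ids, dtype=np.int64)
    node_ids = np.asarray(node_ids, dtype=np.int64)
    tf = np.asarray(tfs, dtype=np.float64)
    df = np.zeros(n_vocab)
    np.add.at(df, node_ids, 1.0)
    idf = np.log(n_edges / df)
    weight = tf * idf[node_ids]
    return Hypergraph(
        node_vocab=list(vocab),
        n_edges=n_edges,
        edge_ids=edge_ids,
        node_ids=node_ids,
        tf=tf,
        weight=weight,
        node_global=np.arange(n_vocab, dtype=np.int64),
        df=df,
        idf=idf,
        k=k,
        record_ids=[r.id for r in records],
    )


def subgraph(graph: Hypergraph, edge_indices: np.ndarray) -> Hypergraph:
    """Sub-hypergraph induced by a subset of edges (local nodes re-compacted)."""
    edge_indices = np.asarray(edge_indices)
    pos = {int(e): j for j, e in enumerate(edge_indices)}
    keep = np.isin(graph.edge_ids, edge_indices)
    old_nodes = graph.node_ids[keep]
    uniq, local = np.unique(old_nodes, return_inverse=True)
    return Hypergraph(
        node_vocab=graph.node_vocab,
        n_edges=len(edge_indices),
        edge_ids=np.array([pos[int(e)] for e in graph.edge_ids[keep]], dtype=np.int64),
        node_ids=local,
        tf=graph.tf[keep],
        weight=graph.weight[keep],
        node_global=graph.node_global[uniq],
        df=graph.df,
        idf=graph.idf,
        k=graph.k,
        record_ids=[graph.record_ids[int(e)] for e in edge_indices] if graph.record_ids else [],
    )


def inference_hypergraph(
    train_graph: Hypergraph,
    new_records: list[PeptideRecord],
    k: int | None = None,
    unk_node: bool = True,
    share_nodes: bool = False,
) -> Hypergraph:
    """Attach unseen sequences to the frozen training vocabulary.

    Each new sequence becomes a hyperedge over the training k-mer nodes it
    contains; unseen k-mers collapse onto the UNK node (disable with
    ``unk_node=False``, in which case a sequence with no known k-mer is an
    error).  df/idf stay frozen from training; the UNK node gets idf 0
    (an unknown k-mer carries no diversity information).

    With ``share_nodes=False`` (default) each edge gets its own copies of
    the nodes, so predictions for a record do not depend on which other
    records share its batch.
    """
    if k is None:
        k = train_graph.k
    _check_lengths(new_records, k)
    vocab_index = {km: i for i, km in enumerate(train_graph.node_vocab)}
    n_vocab = len(train_graph.node_vocab)
    unk_global = n_vocab
    unk_idf = 0.0  # unknown k-mers carry no diversity information

    edge_ids, globals_, tfs, weights = [], [], [], []
    for j, rec in enumerate(new_records):
        counts: dict[int, int] = {}
        for km in kmers(rec.sequence, k):
            gi = vocab_index.get(km)
            if gi is None:
                if not unk_node:
                    continue
                gi = unk_global
            counts[gi] = counts.get(gi, 0) + 1
        if not counts:
            raise ValueError(
                f"record {rec.id}: no k-mers in the training vocabulary and UNK disabled"
            )
        for gi, c in counts.items():
            edge_ids.append(j)
            globals_.append(gi)
            tfs.append(c)
            weights.append(c * (unk_idf if gi == unk_global else train_graph.idf[gi]))

    edge_ids = np.asarray(edge_ids, dtype=np.int64)
    globals_arr = np.asarray(globals_, dtype=np.int64)
    if share_nodes:
        uniq, local = np.unique(globals_arr, return_inverse=True)
        node_global = uniq
    else:
        local = np.arange(len(globals_arr), dtype=np.int64)
        node_global = globals_arr
    return Hypergraph(
        node_vocab=train_graph.node_vocab,
        n_edges=len(new_records),
        edge_ids=edge_ids,
        node_ids=local,
        tf=np.asarray(tfs, dtype=np.float64),
        weight=np.asarray(weights, dtype=np.float64),
        node_global=node_global,
        df=train_graph.df,
        idf=train_graph.idf,
        k=k,
        record_ids=[r.id for r in new_records],
    )


class HyperGATParams(_nn.Module):
    """One attention layer's transforms W_v, W_e, W'_v, W'_e (no biases)."""

    def __init__(self, d_in: int, d_hid: int, rng: np.random.Generator, leaky_slope: float = 0.2):
        self.w_v = _nn.Linear(d_in, d_hid, rng, bias=False)
        self.w_e = _nn.Linear(d_hid, d_hid, rng, bias=False)
        self.wp_v = _nn.Linear(d_in, d_hid, rng, bias=False)
        self.wp_e = _nn.Linear(d_hid, d_hid, rng, bias=False)
        self.leaky_slope = leaky_slope


def edge_update(
    node_feats: Tensor | np.ndarray,
    graph: Hypergraph,
    params: HyperGATParams,
    edge_feats_prev: Tensor | np.ndarray | None = None,
) -> tuple[Tensor, Tensor]:
    """Hyperedge feature update; returns (edge features, per-incidence beta).

    ``edge_feats_prev`` defaults to the plain mean of each edge's member
    node features (the bootstrap used before the first layer).
    """
    h_v = node_feats if isinstance(node_feats, Tensor) else Tensor(node_feats)
    if graph.n_edges == 0:
        raise ValueError("hypergraph has no edges")
    counts = np.zeros(graph.n_edges)
    np.add.at(counts, graph.edge_ids, 1.0)
    if (counts < 1).any():
        raise ValueError("empty hyperedge")
    if edge_feats_prev is None:
        summed = segment_sum(h_v[graph.node_ids], graph.edge_ids, graph.n_edges)
        edge_feats_prev = summed / Tensor(counts[:, None])
    h_e = edge_feats_prev if isinstance(edge_feats_prev, Tensor) else Tensor(edge_feats_prev)

    pv = params.wp_v(h_v)  # (n_nodes, d_hid)
    pe = params.wp_e(h_e)  # (n_edges, d_hid)
    scores = (pv[graph.node_ids] * pe[graph.edge_ids]).sum(axis=-1)
    scores = scores.leaky_relu(params.leaky_slope) * Tensor(graph.weight)
    beta = segment_softmax(scores, graph.edge_ids, graph.n_edges)
    msg = pv[graph.node_ids] * beta.reshape(-1, 1)
    new_edge = segment_sum(msg, graph.edge_ids, graph.n_edges).elu()
    return new_edge, beta


def node_update(
    edge_feats: Tensor | np.ndarray,
    graph: Hypergraph,
    params: HyperGATParams,
    node_feats: Tensor | np.ndarray,
) -> tuple[Tensor, Tensor]:
    """Node feature update; returns (node features, per-incidence alpha)."""
    h_e = edge_feats if isinstance(edge_feats, Tensor) else Tensor(edge_feats)
    h_v = node_feats if isinstance(node_feats, Tensor) else Tensor(node_feats)
    deg = np.zeros(graph.n_nodes)
    np.add.at(deg, graph.node_ids, 1.0)
    if (deg < 1).any():
        raise ValueError("orphan node (no incident hyperedge)")
    tv = params.w_v(h_v)
    te = params.w_e(h_e)
    scores = (tv[graph.node_ids] * te[graph.edge_ids]).sum(axis=-1)
    scores = scores.leaky_relu(params.leaky_slope)
    alpha = segment_softmax(scores, graph.node_ids, graph.n_nodes)
    msg = te[graph.edge_ids] * alpha.reshape(-1, 1)
    new_node = segment_sum(msg, graph.node_ids, graph.n_nodes).elu()
    return new_node, alpha


class HyperGATBranch(_nn.Module):
    """k-mer embeddings + stacked HyperGAT layers + per-sequence readout.

    The embedding table has one row per training k-mer plus a final UNK
    row.  ``n_layers`` (edge update, node update) pairs run first; a
    dedicated readout layer performs a last edge update whose output is
    projected to the branch feature dimension.
    """

    def __init__(
        self,
        n_vocab: int,
        d_hid: int = 64,
        n_layers: int = 2,
        d_fuse: int = 128,
        leaky_slope: float = 0.2,
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.embed = _nn.Embedding(n_vocab + 1, d_hid, rng)  # + UNK row
        self.layers = [
            HyperGATParams(d_hid, d_hid, rng, leaky_slope) for _ in range(n_layers)
        ]
        self.readout = HyperGATParams(d_hid, d_hid, rng, leaky_slope)
        self.proj = _nn.Linear(d_hid, d_fuse, rng)

    def propagate(self, graph: Hypergraph) -> tuple[Tensor, Tensor | None]:
        """Run the (edge update, node update) layer stack; returns (h_v, h_e)."""
        h_v = self.embed(graph.node_global)
        h_e = None
        for layer in self.layers:
            h_e, _ = edge_update(h_v, graph, layer, h_e)
            h_v, _ = node_update(h_e, graph, layer, h_v)
        return h_v, h_e

    def __call__(self, graph: Hypergraph) -> Tensor:
        h_v, _ = self.propagate(graph)
        h_e, _ = edge_update(h_v, graph, self.readout, None)
        return self.proj(h_e)

    def node_feature_cache(self, graph: Hypergraph) -> np.ndarray:
        """Propagated node features for every vocabulary k-mer plus UNK.

        Row i is the post-propagation feature of vocabulary node i on the
        (training) graph; the final row is the raw UNK embedding.  Unseen
        sequences are read out against this cache, which keeps per-sequence
        predictions independent of batch composition while still carrying
        the relational information learned on the training hypergraph.
        """
        h_v, _ = self.propagate(graph)
        cache = self.embed.weight.data.copy()
        cache[graph.node_global] = h_v.data
        return cache

    def readout_from_cache(self, graph: Hypergraph, cache: np.ndarray) -> Tensor:
        """Per-sequence branch features for an inference graph."""
        h_v = Tensor(cache[graph.node_global])
        h_e, _ = edge_update(h_v, graph, self.readout, None)
        return self.proj(h_e)


def hypergat_forward(
    graph: Hypergraph, node_init: np.ndarray, params: list[HyperGATParams],
    readout: HyperGATParams, proj: _nn.Linear,
) -> np.ndarray:
    """Functional forward over explicit node features (per-sequence output).

    Mirrors :class:`HyperGATBranch` but takes the initial node feature
    matrix directly, which makes relabeling-invariance and oracle checks
    straightforward.
    """
    h_v: Tensor = Tensor(node_init)
    h_e = None
    for layer in params:
        h_e, _ = edge_update(h_v, graph, layer, h_e)
        h_v, _ = node_update(h_e, graph, layer, h_v)
    h_e, _ = edge_update(h_v, graph, readout, None)
    return proj(h_e).data


__all__.append("subgraph")
__all__.append("hypergat_forward")
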