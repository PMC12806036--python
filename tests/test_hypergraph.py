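"""k-mers, hypergraph construction and HyperGAT attention updates."""

import numpy as np
import pytest

from amhf.hypergraph import (
    HyperGATBranch,
    HyperGATParams,
    build_hypergraph,
    edge_update,
    hypergat_forward,
    inference_hypergraph,
    kmers,
    node_update,
)
from amhf.io import PeptideRecord
from conftest import random_hypergraph
from oracles import naive_edge_update, naive_node_update


def _records(sequences):
    return [
        PeptideRecord(f"r{i}", s, np.array([1], dtype=np.int8))
        for i, s in enumerate(sequences)
    ]


class TestKmers:
    def test_three_mers(self):
        assert kmers("PAMNH", 3) == ["PAM", "AMN", "MNH"]

    def test_two_mers(self):
        out = kmers("PAMNH", 2)
        assert out == ["PA", "AM", "MN", "NH"]
        assert {"AM", "MN"} <= set(out)

    def test_k_equals_length(self):
        assert kmers("PAMNH", 5) == ["PAMNH"]

    @pytest.mark.parametrize("k", [0, -1, 6])
    def test_bad_k(self, k):
        with pytest.raises(ValueError):
            kmers("PAMNH", k)


class TestBuildHypergraph:
    def test_shared_subsequences_connect_edges(self):
        graph = build_hypergraph(_records(["SKIVGAFD", "VGALLDKA", "FDGSLKA"]), k=2)
        H = graph.incidence_matrix()
        idx = {km: i for i, km in enumerate(graph.node_vocab)}
        assert list(H[:, idx["VG"]]) == [1, 1, 0]
        assert list(H[:, idx["FD"]]) == [1, 0, 1]
        graph.validate()

    def test_incidence_consistency(self):
        records = _records(["SKIVGAFD", "VGALLDKA", "FDGSLKA", "AAAAA"])
        graph = build_hypergraph(records, k=2)
        H = graph.incidence_matrix()
        for j, rec in enumerate(records):
            assert H[j].sum() == len(set(kmers(rec.sequence, 2)))
        assert np.array_equal(H.sum(axis=0).astype(float), graph.df)

    def test_single_sequence_idf_zero(self):
        graph = build_hypergraph(_records(["PAMNH"]), k=2)
        H = graph.incidence_matrix()
        assert H.shape[0] == 1 and (H == 1).all()
        assert np.allclose(graph.idf, 0.0)

    def test_duplicate_sequences_identical_rows(self):
        graph = build_hypergraph(_records(["KWKLF", "KWKLF"]), k=2)
        H = graph.incidence_matrix()
        assert np.array_equal(H[0], H[1])

    def test_too_short_sequence_lists_ids(self):
        with pytest.raises(ValueError, match="r1"):
            build_hypergraph(_records(["KWKLFKK", "ACD"]), k=5)

    def test_vocab_first_occurrence_order(self):
        graph = build_hypergraph(_records(["PAMNH"]), k=3)
        assert graph.node_vocab == ["PAM", "AMN", "MNH"]


class TestAttentionUpdates:
    def test_single_member_edge_beta_one(self):
        rng = np.random.default_rng(0)
        graph, H, W = random_hypergraph(rng)
        params = HyperGATParams(4, 4, rng)
        feats = rng.normal(size=(graph.n_nodes, 4))
        _, beta = edge_update(feats, graph, params)
        for e in range(graph.n_edges):
            members = beta.data[graph.edge_ids == e]
            if len(members) == 1:
                assert members[0] == pytest.approx(1.0)

    def test_attention_sums_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            graph, H, W = random_hypergraph(rng)
            params = HyperGATParams(4, 4, rng)
            feats = rng.normal(size=(graph.n_nodes, 4))
            h_e, beta = edge_update(feats, graph, params)
            _, alpha = node_update(h_e, graph, params, feats)
            bsum = np.zeros(graph.n_edges)
            np.add.at(bsum, graph.edge_ids, beta.data)
            asum = np.zeros(graph.n_nodes)
            np.add.at(asum, graph.node_ids, alpha.data)
            assert np.abs(bsum - 1).max() < 1e-6
            assert np.abs(asum - 1).max() < 1e-6

    def test_updates_match_naive_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            graph, H, W = random_hypergraph(rng)
            params = HyperGATParams(4, 4, rng)
            h_v = rng.normal(size=(graph.n_nodes, 4))
            h_e0 = rng.normal(size=(graph.n_edges, 4))
            mine_e, beta = edge_update(h_v, graph, params, h_e0)
            ref_e, ref_beta = naive_edge_update(
                H, W, h_v, h_e0,
                params.wp_v.weight.data, params.wp_e.weight.data, params.leaky_slope,
            )
            assert np.abs(mine_e.data - ref_e).max() < 1e-6
            assert np.abs(
                beta.data - ref_beta[graph.edge_ids, graph.node_ids]
            ).max() < 1e-6
            mine_v, alpha = node_update(mine_e, graph, params, h_v)
            ref_v, ref_alpha = naive_node_update(
                H, ref_e, h_v,
                params.w_v.weight.data, params.w_e.weight.data, params.leaky_slope,
            )
            assert np.abs(mine_v.data - ref_v).max() < 1e-6
            assert np.abs(
                alpha.data - ref_alpha[graph.edge_ids, graph.node_ids]
            ).max() < 1e-6


class TestForward:
    def _branch_params(self, rng, d=4):
        layers = [HyperGATParams(d, d, rng) for _ in range(2)]
        readout = HyperGATParams(d, d, rng)
        from amhf._nn import Linear

        proj = Linear(d, 3, rng)
        return layers, readout, proj

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        graph, H, W = random_hypergraph(rng)
        layers, readout, proj = self._branch_params(rng)
        feats = rng.normal(size=(graph.n_nodes, 4))
        out = hypergat_forward(graph, feats, layers, readout, proj)
        perm = rng.permutation(graph.n_nodes)
        inv = np.argsort(perm)
        import dataclasses

        permuted = dataclasses.replace(
            graph,
            node_ids=inv[graph.node_ids],
            node_global=np.arange(graph.n_nodes, dtype=np.int64),
            df=graph.df[perm],
            idf=graph.idf[perm],
            node_vocab=[graph.node_vocab[i] for i in perm],
        )
        out_p = hypergat_forward(permuted, feats[perm], layers, readout, proj)
        assert np.abs(out - out_p).max() < 1e-6

    def test_duplicate_sequences_identical_features(self):
        rng = np.random.default_rng(4)
        graph = build_hypergraph(_records(["KWKLFKK", "KWKLFKK", "ACDEFGH"]), k=3)
        branch = HyperGATBranch(len(graph.node_vocab), d_hid=6, n_layers=2,
                                d_fuse=5, rng=rng)
        out = branch(graph).data
        assert np.abs(out[0] - out[1]).max() < 1e-6
        assert out.shape == (3, 5)


class TestInferenceGraph:
    @pytest.fixture()
    def train_graph(self):
        return build_hypergraph(_records(["SKIVGAFD", "VGALLDKA", "FDGSLKA"]), k=2)

    def test_known_kmers_only(self, train_graph):
        g = inference_hypergraph(train_graph, _records(["SKIV"]), k=2)
        unk = len(train_graph.node_vocab)
        assert (g.node_global != unk).all()
        assert g.n_edges == 1

    def test_novel_kmer_maps_to_unk(self, train_graph):
        g = inference_hypergraph(train_graph, _records(["SKWW"]), k=2)
        unk = len(train_graph.node_vocab)
        assert (g.node_global == unk).sum() >= 1

    def test_empty_batch(self, train_graph):
        g = inference_hypergraph(train_graph, [], k=2)
        assert g.n_edges == 0 and len(g.edge_ids) == 0

    def test_unknown_only_with_unk_disabled(self, train_graph):
        with pytest.raises(ValueError, match="UNK"):
            inference_hypergraph(train_graph, _records(["WWWW"]), k=2, unk_node=False)

    def test_frozen_idf(self, train_graph):
        g = inference_hypergraph(train_graph, _records(["SKIV"]), k=2)
        idx = {km: i for i, km in enumerate(train_graph.node_vocab)}
        for local, (gi, w) in enumerate(zip(g.node_global, g.weight)):
            km = train_graph.node_vocab[gi]
            assert w == pytest.approx(g.tf[local] * train_graph.idf[idx[km]])
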