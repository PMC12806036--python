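"""Positional encoding, self-attention, TextCNN and the sequence branch."""

import numpy as np
import pytest

from amhf import _nn
from amhf._tensor import Tensor
from amhf.sequence import SequenceBranch, encode_batch, positional_embedding


class TestPositionalEmbedding:
    def test_row_zero_alternates(self):
        P = positional_embedding(4, 6)
        assert np.allclose(P[0], [0, 1, 0, 1, 0, 1])

    def test_default_shape_and_bounds(self):
        P = positional_embedding(50, 192)
        assert P.shape == (50, 192)
        assert np.abs(P).max() <= 1.0

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            positional_embedding(10, 7)


class TestMhsa:
    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        attn = _nn.MultiHeadSelfAttention(8, 2, rng)
        x = Tensor(rng.normal(size=(3, 5, 8)))
        attn(x)
        sums = attn.last_attention.sum(axis=-1)
        assert np.abs(sums - 1.0).max() < 1e-6

    def test_single_position_attends_itself(self):
        rng = np.random.default_rng(1)
        attn = _nn.MultiHeadSelfAttention(8, 2, rng)
        attn(Tensor(rng.normal(size=(2, 1, 8))))
        assert np.allclose(attn.last_attention, 1.0)

    def test_masked_keys_get_zero_weight(self):
        rng = np.random.default_rng(2)
        attn = _nn.MultiHeadSelfAttention(8, 2, rng)
        mask = np.ones((2, 6), dtype=bool)
        mask[:, 4:] = False
        attn(Tensor(rng.normal(size=(2, 6, 8))), mask)
        assert np.abs(attn.last_attention[:, :, :, 4:]).max() < 1e-9

    def test_all_pad_row_rejected(self):
        rng = np.random.default_rng(3)
        attn = _nn.MultiHeadSelfAttention(8, 2, rng)
        with pytest.raises(ValueError):
            attn(Tensor(rng.normal(size=(1, 4, 8))), np.zeros((1, 4), dtype=bool))

    def test_dimension_head_mismatch(self):
        with pytest.raises(ValueError):
            _nn.MultiHeadSelfAttention(10, 3, np.random.default_rng(0))


class TestTextCnn:
    def test_output_width(self):
        rng = np.random.default_rng(0)
        cnn = _nn.TextCNN(6, [2, 3, 4, 5], 7, rng)
        out = cnn(Tensor(rng.normal(size=(3, 12, 6))))
        assert out.shape == (3, 28)

    def test_translation_of_planted_pattern(self):
        """Max pooling makes the response position-independent (away from edges)."""
        rng = np.random.default_rng(4)
        cnn = _nn.TextCNN(4, [3], 5, rng)
        pattern = rng.normal(size=(3, 4))
        a = np.zeros((1, 20, 4))
        b = np.zeros((1, 20, 4))
        a[0, 2:5] = pattern
        b[0, 11:14] = pattern
        out_a = cnn(Tensor(a)).data
        out_b = cnn(Tensor(b)).data
        assert np.abs(out_a - out_b).max() < 1e-9

    def test_zero_input_gives_bias_response(self):
        rng = np.random.default_rng(5)
        cnn = _nn.TextCNN(4, [2, 3], 6, rng)
        out = cnn(Tensor(np.zeros((2, 10, 4)))).data
        expected = np.concatenate(
            [np.maximum(conv.bias.data, 0.0) for conv in cnn.convs]
        )
        assert np.allclose(out, expected[None, :])

    def test_too_short_sequence(self):
        rng = np.random.default_rng(6)
        cnn = _nn.TextCNN(4, [2, 5], 3, rng)
        with pytest.raises(ValueError):
            cnn(Tensor(np.zeros((1, 4, 4))))


@pytest.fixture(scope="module")
def branch():
    return SequenceBranch(n=50, d=16, heads=4, filters_per_size=4, d_fuse=10,
                          rng=np.random.default_rng(0))


class TestSequenceBranch:

    def test_output_shape_any_length(self, branch):
        res, struct = encode_batch(["ACDEF", "KWKLFKKIEK" * 5], n=50)
        out = branch(res, struct)
        assert out.shape == (2, 10)

    def test_eval_deterministic(self, branch):
        res, struct = encode_batch(["ACDEFKW"], n=50)
        a = branch(res, struct).data
        b = branch(res, struct).data
        assert np.array_equal(a, b)

    def test_batch_order_equivariance(self, branch):
        seqs = ["ACDEF", "KWKLF", "GGGGGG", "MNHPA"]
        res, struct = encode_batch(seqs, n=50)
        out = branch(res, struct).data
        perm = [2, 0, 3, 1]
        out_p = branch(res[perm], struct[perm]).data
        assert np.abs(out_p - out[perm]).max() < 1e-9
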