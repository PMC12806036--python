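"""Amino-acid sequence branch: embeddings, self-attention and TextCNN.

Two parallel pathways over the length-50 encoded peptide:

* residue pathway — learned residue embedding plus fixed sinusoidal
  positional embedding, a multi-head self-attention block (with Add&Norm),
  then multi-width text convolutions (filter widths 2-5, chosen to match
  the minimum peptide length of 5) with global max pooling;
* structure pathway — Chou-Fasman secondary-structure classes embedded the
  same way but passed only through the TextCNN (the heuristic structure
  labels are noisy, so the deliberately simpler pathway avoids
  over-interpreting them).

The pooled features of both pathways are concatenated and integrated by a
feed-forward block into a fixed-dimension branch feature.
"""

from __future__ import annotations

import numpy as np

from . import _nn
from ._tensor import Tensor, concat
from .io import encode_residues
from .structure import chou_fasman

__all__ = [
    "positional_embedding",
    "encode_structure",
    "SequenceBranch",
]

#: pad id for structure sequences (classes 0..3 are stored as ids 1..4)
STRUCT_PAD = 0


def positional_embedding(n: int, d: int) -> np.ndarray:
    """Fixed sinusoidal position matrix; see :func:`amhf._nn.sinusoidal_positions`."""
    return _nn.sinusoidal_positions(n, d)


def encode_structure(sequence: str, n: int = 50) -> np.ndarray:
    """Chou-Fasman classes aligned to :func:`amhf.io.encode_residues` padding.

    Structure class ``c`` at position ``i`` is stored as id ``c + 1``;
    positions past the (possibly truncated) sequence carry the pad id 0.
    """
    classes = chou_fasman(sequence[:n])
    out = np.zeros(n, dtype=np.int64)
    out[: len(classes)] = classes + 1
    return out


class SequenceBranch(_nn.Module):
    """Residue path (embed + MHSA + TextCNN) merged with structure path."""

    def __init__(
        self,
        n: int = 50,
        d: int = 192,
        heads: int = 8,
        filters_per_size: int = 64,
        filter_widths: tuple[int, ...] = (2, 3, 4, 5),
        d_fuse: int = 128,
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        if max(filter_widths) > n:
            raise ValueError("max filter width exceeds sequence length")
        self.res_embed = _nn.Embedding(21, d, rng)  # 20 residues + pad
        self.struct_embed = _nn.Embedding(5, d, rng)  # 4 classes + pad
        self.pos = Tensor(positional_embedding(n, d))
        self.attn = _nn.MultiHeadSelfAttention(d, heads, rng)
        self.res_cnn = _nn.TextCNN(d, list(filter_widths), filters_per_size, rng)
        self.struct_cnn = _nn.TextCNN(d, list(filter_widths), filters_per_size, rng)
        width = 2 * len(filter_widths) * filters_per_size
        self.ff1 = _nn.Linear(width, d_fuse, rng)
        self.ff2 = _nn.Linear(d_fuse, d_fuse, rng)

    def __call__(self, residue_ids: np.ndarray, structure_ids: np.ndarray) -> Tensor:
        residue_ids = np.atleast_2d(residue_ids)
        structure_ids = np.atleast_2d(structure_ids)
        pad_mask = residue_ids > 0
        x = self.res_embed(residue_ids) + self.pos
        x = self.attn(x, pad_mask)
        feats_res = self.res_cnn(x)
        s = self.struct_embed(structure_ids) + self.pos
        feats_struct = self.struct_cnn(s)
        h = concat([feats_res, feats_struct], axis=-1)
        return self.ff2(self.ff1(h).relu())


def encode_batch(sequences: list[str], n: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Residue-id and structure-id matrices for a list of peptides."""
    res = np.stack([encode_residues(s, n) for s in sequences])
    struct = np.stack([encode_structure(s, n) for s in sequences])
    return res, struct


__all__.append("encode_batch")
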