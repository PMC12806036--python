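"""Atomic-level branch: peptide -> SMILES -> tokens -> transformer feature.

The finest-grained view of a peptide is its atomic composition.  A peptide
sequence is converted to the SMILES of the linear polymer (condensation of
per-residue units, one water lost per peptide bond), tokenized with the
standard SMILES regex convention, and encoded by a pluggable sequence
encoder whose output feeds a two-fully-connected-layer head with dropout.

The residue SMILES table below writes each residue as a backbone unit
``N[C@@H](<side chain>)C(=O)`` (glycine and proline special-cased); the
concatenation of units plus a terminal hydroxyl is the peptide.  The units
carry L-amino-acid stereochemistry and are canonical-equivalent to a
cheminformatics toolkit's sequence-to-molecule conversion, which serves as
an independent oracle in the test suite.

The default encoder is a small randomly initialized transformer with the
same multi-head self-attention + feed-forward block structure as BERT-style
encoders; any object implementing :class:`EncoderContract` (an ``encode``
method and a ``d_atom`` attribute) can replace it, e.g. a pretrained
scientific-text model.
"""

from __future__ import annotations

import re

import numpy as np

from . import _nn
from ._tensor import Tensor, dropout
from .io import validate_sequence

__all__ = [
    "RESIDUE_SMILES_UNITS",
    "RESIDUE_FORMULAS",
    "WATER_FORMULA",
    "peptide_to_smiles",
    "tokenize_smiles",
    "SmilesVocabulary",
    "TinyTransformerEncoder",
    "AtomicBranch",
]

_SIDE_CHAINS = {
    "A": "C",
    "R": "CCCNC(=N)N",
    "N": "CC(N)=O",
    "D": "CC(=O)O",
    "C": "CS",
    "Q": "CCC(N)=O",
    "E": "CCC(=O)O",
    "H": "Cc1c[nH]cn1",
    "I": "[C@@H](C)CC",
    "L": "CC(C)C",
    "K": "CCCCN",
    "M": "CCSC",
    "F": "Cc1ccccc1",
    "S": "CO",
    "T": "[C@@H](C)O",
    "W": "Cc1c[nH]c2ccccc12",
    "Y": "Cc1ccc(O)cc1",
    "V": "C(C)C",
}

#: Backbone unit contributed by each residue (ends at the carbonyl carbon).
RESIDUE_SMILES_UNITS = {
    aa: ("NCC(=O)" if aa == "G" else "N1CCC[C@H]1C(=O)" if aa == "P"
         else f"N[C@@H]({side})C(=O)")
    for aa, side in list(_SIDE_CHAINS.items()) + [("G", ""), ("P", "")]
}

#: Molecular formula of each free amino acid (element -> atom count).
RESIDUE_FORMULAS = {
    "A": {"C": 3, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 7, "N": 1, "O": 2, "S": 1},
    "D": {"C": 4, "H": 7, "N": 1, "O": 4},
    "E": {"C": 5, "H": 9, "N": 1, "O": 4},
    "F": {"C": 9, "H": 11, "N": 1, "O": 2},
    "G": {"C": 2, "H": 5, "N": 1, "O": 2},
    "H": {"C": 6, "H": 9, "N": 3, "O": 2},
    "I": {"C": 6, "H": 13, "N": 1, "O": 2},
    "K": {"C": 6, "H": 14, "N": 2, "O": 2},
    "L": {"C": 6, "H": 13, "N": 1, "O": 2},
    "M": {"C": 5, "H": 11, "N": 1, "O": 2, "S": 1},
    "N": {"C": 4, "H": 8, "N": 2, "O": 3},
    "P": {"C": 5, "H": 9, "N": 1, "O": 2},
    "Q": {"C": 5, "H": 10, "N": 2, "O": 3},
    "R": {"C": 6, "H": 14, "N": 4, "O": 2},
    "S": {"C": 3, "H": 7, "N": 1, "O": 3},
    "T": {"C": 4, "H": 9, "N": 1, "O": 3},
    "V": {"C": 5, "H": 11, "N": 1, "O": 2},
    "W": {"C": 11, "H": 12, "N": 2, "O": 2},
    "Y": {"C": 9, "H": 11, "N": 1, "O": 3},
}

WATER_FORMULA = {"H": 2, "O": 1}


def peptide_to_smiles(sequence: str) -> str:
    """SMILES of the linear peptide (one water lost per peptide bond)."""
    validate_sequence(sequence)
    return "".join(RESIDUE_SMILES_UNITS[aa] for aa in sequence) + "O"


_TOKEN_RE = re.compile(r"\[[^\]]*\]|Cl|Br|.")


def tokenize_smiles(smiles: str) -> list[str]:
    """Tokenize SMILES: bracket atoms and two-letter elements are single tokens.

    Rejoining the tokens reproduces the input.  Unbalanced brackets or
    parentheses raise ``ValueError``.
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    for opener, closer in ("[]", "()"):
        depth = 0
        for ch in smiles:
            if ch == opener:
                depth += 1
            elif ch == closer:
                depth -= 1
                if depth < 0:
                    raise ValueError(f"unbalanced {closer!r} in SMILES: {smiles!r}")
        if depth != 0:
            raise ValueError(f"unbalanced {opener!r} in SMILES: {smiles!r}")
    return _TOKEN_RE.findall(smiles)


class SmilesVocabulary:
    """Token <-> id map with pad (0) and unknown (1) entries."""

    PAD = 0
    UNK = 1

    def __init__(self, tokens: list[str]):
        uniq: dict[str, None] = {}
        for t in tokens:
            uniq.setdefault(t, None)
        self.tokens = ["<pad>", "<unk>"] + list(uniq)
        self._index = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    @classmethod
    def from_sequences(cls, smiles_list: list[str]) -> "SmilesVocabulary":
        toks: list[str] = []
        for s in smiles_list:
            toks.extend(tokenize_smiles(s))
        return cls(toks)

    def encode(self, tokens: list[str], length: int) -> np.ndarray:
        """Pad/truncate a token list to ``length`` integer ids."""
        out = np.zeros(length, dtype=np.int64)
        for i, t in enumerate(tokens[:length]):
            out[i] = self._index.get(t, self.UNK)
        return out


class TinyTransformerEncoder(_nn.Module):
    """Small random-init transformer encoder satisfying the encoder contract.

    ``encode`` maps padded token-id batches to fixed-dimension features by
    mean-pooling the final hidden states over non-pad positions.  With fixed
    weights and no dropout the output is deterministic, and each sequence's
    feature is independent of its batch companions.
    """

    def __init__(
        self,
        vocab_size: int,
        d_atom: int = 64,
        heads: int = 4,
        n_layers: int = 2,
        max_len: int = 256,
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.d_atom = d_atom
        self.deterministic_eval = True
        self.embed = _nn.Embedding(vocab_size, d_atom, rng)
        self.pos = Tensor(_nn.sinusoidal_positions(max_len, d_atom))
        self.blocks = [
            _nn.TransformerBlock(d_atom, heads, 2 * d_atom, rng) for _ in range(n_layers)
        ]

    def encode(self, token_ids: np.ndarray, pad_mask: np.ndarray | None = None) -> Tensor:
        token_ids = np.atleast_2d(token_ids)
        if pad_mask is None:
            pad_mask = token_ids != SmilesVocabulary.PAD
        x = self.embed(token_ids) + self.pos[: token_ids.shape[1]]
        for block in self.blocks:
            x = block(x, pad_mask)
        valid = pad_mask.astype(np.float64)
        pooled = (x * Tensor(valid[:, :, None])).sum(axis=1)
        return pooled / Tensor(np.maximum(valid.sum(axis=1), 1.0)[:, None])


class AtomicBranch(_nn.Module):
    """Encoder output -> FC -> ReLU -> dropout -> FC -> branch feature."""

    def __init__(
        self,
        encoder,
        d_hidden: int,
        d_fuse: int,
        dropout_rate: float,
        rng: np.random.Generator,
    ):
        if not hasattr(encoder, "encode") or not hasattr(encoder, "d_atom"):
            raise TypeError("encoder must provide .encode(...) and .d_atom")
        self.encoder = encoder
        self.fc1 = _nn.Linear(encoder.d_atom, d_hidden, rng)
        self.fc2 = _nn.Linear(d_hidden, d_fuse, rng)
        self.dropout_rate = dropout_rate

    def __call__(
        self,
        token_ids: np.ndarray,
        pad_mask: np.ndarray | None = None,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        h = self.encoder.encode(token_ids, pad_mask)
        h = self.fc1(h).relu()
        h = dropout(h, self.dropout_rate, rng if rng is not None else np.random.default_rng(0), training)
        return self.fc2(h)
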