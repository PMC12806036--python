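"""SMILES conversion (vs the cheminformatics-toolkit oracle) and tokenizer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem
from rdkit.Chem.rdMolDescriptors import CalcMolFormula

from amhf._tensor import Tensor
from amhf.atomic import (
    RESIDUE_FORMULAS,
    WATER_FORMULA,
    AtomicBranch,
    SmilesVocabulary,
    TinyTransformerEncoder,
    peptide_to_smiles,
    tokenize_smiles,
)
from amhf.io import AMINO_ACIDS

peptides = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=12)


def _formula(smiles: str) -> dict[str, int]:
    import re

    text = CalcMolFormula(Chem.MolFromSmiles(smiles))
    return {el: int(n) if n else 1 for el, n in re.findall(r"([A-Z][a-z]?)(\d*)", text)}


class TestPeptideToSmiles:
    def test_glycine(self):
        smiles = peptide_to_smiles("G")
        assert _formula(smiles) == {"C": 2, "H": 5, "N": 1, "O": 2}
        assert Chem.CanonSmiles(smiles) == Chem.MolToSmiles(Chem.MolFromSequence("G"))

    def test_glycylglycine_loses_one_water(self):
        smiles = peptide_to_smiles("GG")
        assert _formula(smiles) == {"C": 4, "H": 8, "N": 2, "O": 3}

    def test_invalid_residue(self):
        with pytest.raises(ValueError):
            peptide_to_smiles("GX")

    @pytest.mark.parametrize("aa", sorted(AMINO_ACIDS))
    def test_homodipeptide_formula_conservation(self, aa):
        expected = {
            el: 2 * RESIDUE_FORMULAS[aa].get(el, 0) - WATER_FORMULA.get(el, 0)
            for el in set(RESIDUE_FORMULAS[aa]) | set(WATER_FORMULA)
        }
        expected = {el: n for el, n in expected.items() if n}
        assert _formula(peptide_to_smiles(aa + aa)) == expected

    @given(seq=peptides)
    @settings(max_examples=30, deadline=None)
    def test_canonical_equivalent_to_toolkit(self, seq):
        assert Chem.CanonSmiles(peptide_to_smiles(seq)) == Chem.MolToSmiles(
            Chem.MolFromSequence(seq)
        )


class TestTokenizer:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("C(=O)O", ["C", "(", "=", "O", ")", "O"]),
            ("[NH3+]C", ["[NH3+]", "C"]),
            ("CCl", ["C", "Cl"]),
        ],
    )
    def test_examples(self, smiles, expected):
        assert tokenize_smiles(smiles) == expected

    @pytest.mark.parametrize("bad", ["[NH3+C", "C(=O))O", "C(C", "]C["])
    def test_unbalanced(self, bad):
        with pytest.raises(ValueError):
            tokenize_smiles(bad)

    @given(seq=peptides)
    @settings(max_examples=50, deadline=None)
    def test_rejoin_identity(self, seq):
        smiles = peptide_to_smiles(seq)
        assert "".join(tokenize_smiles(smiles)) == smiles


@pytest.fixture(scope="module")
def branch():
    rng = np.random.default_rng(0)
    vocab = SmilesVocabulary.from_sequences(
        [peptide_to_smiles(s) for s in ("ACDEF", "KWKLF", "GGGGG")]
    )
    enc = TinyTransformerEncoder(len(vocab), d_atom=16, heads=2, n_layers=1,
                                 max_len=64, rng=rng)
    return vocab, AtomicBranch(enc, d_hidden=24, d_fuse=12, dropout_rate=0.3, rng=rng)


class TestAtomicBranch:

    def test_output_shape(self, branch):
        vocab, br = branch
        ids = np.stack([vocab.encode(tokenize_smiles(peptide_to_smiles(s)), 64)
                        for s in ("ACDEF", "KWKLF")])
        out = br(ids, training=False)
        assert out.shape == (2, 12)

    def test_batch_invariance_in_eval(self, branch):
        vocab, br = branch
        seqs = ["ACDEF", "KWKLF", "GGGGG", "ACKWG"] * 2
        ids = np.stack([vocab.encode(tokenize_smiles(peptide_to_smiles(s)), 64)
                        for s in seqs])
        full = br(ids, training=False).data
        solo = br(ids[:1], training=False).data
        assert np.abs(full[0] - solo[0]).max() < 1e-6

    def test_distinct_peptides_distinct_features(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vocab = SmilesVocabulary.from_sequences(
                [peptide_to_smiles(s) for s in ("ACDEF", "KWKLF")]
            )
            enc = TinyTransformerEncoder(len(vocab), 8, 2, 1, 64, rng)
            br = AtomicBranch(enc, 8, 8, 0.0, rng)
            ids = np.stack([vocab.encode(tokenize_smiles(peptide_to_smiles(s)), 64)
                            for s in ("ACDEF", "KWKLF")])
            out = br(ids, training=False).data
            if np.abs(out[0] - out[1]).max() > 1e-8:
                hits += 1
        assert hits == 20

    def test_encoder_contract_enforced(self):
        with pytest.raises(TypeError):
            AtomicBranch(object(), 8, 8, 0.0, np.random.default_rng(0))

    def test_pluggable_encoder_keeps_shapes(self):
        class FixedEncoder:
            d_atom = 16
            deterministic_eval = True

            def encode(self, ids, mask=None):
                return Tensor(np.ones((len(np.atleast_2d(ids)), 16)))

        br = AtomicBranch(FixedEncoder(), 8, 12, 0.0, np.random.default_rng(0))
        out = br(np.zeros((3, 64), dtype=np.int64), training=False)
        assert out.shape == (3, 12)
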