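"""Molecule parsing, canonicalization, SELFIES conversion, tokenization."""

import numpy as np
import pytest
from rdkit import Chem

from textmol import selfies_codec
from textmol.chem import (ConversionError, MoleculeError, ReprKind,
                          canonicalize, parse_molecule, selfies_to_smiles,
                          smiles_to_selfies, strip_stereo)
from textmol.tokenizer import (PAD, BOS, EOS, TokenizationError, build_vocab,
                               detokenize, split_smiles, tokenize)

from conftest import FIXTURE_SMILES, scrambled_variants

PHENOL = "Cc1ccc(O)cc1"
PHENOL_SELFIES = "[C][C][=C][C][=C][Branch1][Branch1][C][=C][Ring1][=Branch1][O]"


class TestParseMolecule:
    def test_valid_smiles(self):
        mol = parse_molecule(PHENOL, ReprKind.SMILES)
        assert mol.is_valid and mol.canonical_smiles is not None

    def test_unclosed_branch_is_invalid(self):
        mol = parse_molecule("C(", ReprKind.SMILES)
        assert not mol.is_valid and mol.canonical_smiles is None

    def test_eos_first_selfies_is_invalid(self):
        mol = parse_molecule("[EOS][C][C]", ReprKind.SELFIES)
        assert not mol.is_valid

    def test_empty_string_rejected(self):
        with pytest.raises(MoleculeError):
            parse_molecule("", ReprKind.SMILES)

    def test_selfies_decodes_before_validation(self):
        mol = parse_molecule("[C][C]", ReprKind.SELFIES)
        assert mol.is_valid and mol.canonical_smiles == "CC"


class TestCanonicalize:
    def test_canonical_form_is_fixed_point(self):
        canonical = canonicalize(parse_molecule(PHENOL))
        again = canonicalize(parse_molecule(canonical))
        assert canonical == again

    def test_atom_ordering_invariance(self):
        assert canonicalize(parse_molecule("OC1=CC=C(C)C=C1")) == \
            canonicalize(parse_molecule(PHENOL))

    def test_methane(self):
        assert canonicalize(parse_molecule("C")) == "C"

    def test_invalid_molecule_raises(self):
        with pytest.raises(MoleculeError):
            canonicalize(parse_molecule("C("))

    @pytest.mark.parametrize("smiles", FIXTURE_SMILES)
    def test_scrambled_inputs_share_canonical_form(self, smiles):
        reference = canonicalize(parse_molecule(smiles))
        for variant in scrambled_variants(smiles, 3, seed=11):
            assert canonicalize(parse_molecule(variant)) == reference

    def test_strip_stereo_switch(self):
        assert "@" not in strip_stereo("C[C@H](N)C(=O)O")
        assert Chem.CanonSmiles(strip_stereo("C[C@H](N)C(=O)O")) == \
            Chem.CanonSmiles("CC(N)C(=O)O")


class TestSelfiesConversion:
    def test_printed_phenol_selfies_decodes_to_phenol(self):
        assert Chem.CanonSmiles(selfies_to_smiles(PHENOL_SELFIES)) == \
            Chem.CanonSmiles(PHENOL)

    def test_round_trip_preserves_canonical_smiles(self):
        selfies = smiles_to_selfies(PHENOL)
        assert Chem.CanonSmiles(selfies_to_smiles(selfies)) == \
            Chem.CanonSmiles(PHENOL)

    def test_two_carbons(self):
        assert selfies_to_smiles("[C][C]") == "CC"

    @pytest.mark.parametrize("smiles", FIXTURE_SMILES)
    def test_fixture_round_trips(self, smiles):
        reference = Chem.CanonSmiles(smiles)
        back = selfies_to_smiles(smiles_to_selfies(smiles))
        assert Chem.CanonSmiles(back) == reference

    def test_invalid_input_raises(self):
        with pytest.raises(ConversionError):
            smiles_to_selfies("C(")
        with pytest.raises(ConversionError):
            selfies_to_smiles("not selfies")

    def test_robustness_random_streams_all_decode(self):
        """Any stream of alphabet tokens yields a parseable molecule."""
        rng = np.random.default_rng(5)
        alphabet = ["[C]", "[=C]", "[#C]", "[O]", "[=O]", "[N]", "[=N]",
                    "[F]", "[Cl]", "[S]", "[Branch1]", "[=Branch1]",
                    "[Ring1]", "[Ring2]", "[Branch2]"]
        for _ in range(500):
            stream = "".join(rng.choice(alphabet,
                                        size=int(rng.integers(1, 25))))
            smiles = selfies_codec.decode(stream)
            if smiles:
                assert Chem.MolFromSmiles(smiles) is not None


def test_random_selfies_beat_random_smiles_validity():
    """Sampled SELFIES streams are essentially always valid; SMILES token
    soup of the same length is not."""
    rng = np.random.default_rng(17)
    selfies_alphabet = ["[C]", "[=C]", "[O]", "[N]", "[F]", "[Branch1]",
                        "[Ring1]", "[=Branch1]"]
    smiles_alphabet = ["C", "c", "O", "N", "F", "(", ")", "=", "1", "2"]
    n = 500
    selfies_valid = 0
    smiles_valid = 0
    for _ in range(n):
        length = int(rng.integers(4, 16))
        s_stream = "".join(rng.choice(selfies_alphabet, size=length))
        if parse_molecule(s_stream, ReprKind.SELFIES).is_valid:
            selfies_valid += 1
        m_stream = "".join(rng.choice(smiles_alphabet, size=length))
        if parse_molecule(m_stream, ReprKind.SMILES).is_valid:
            smiles_valid += 1
    assert selfies_valid / n > smiles_valid / n
    assert selfies_valid / n > 0.95


class TestTokenizer:
    def test_two_carbons_toy_vocab(self):
        vocab = build_vocab(["CC", "CO"], ReprKind.SMILES)
        assert len(vocab) == 5  # C, O + PAD/BOS/EOS
        seq = tokenize("CC", vocab)
        assert seq.ids == (vocab.bos_index, vocab.index("C"),
                           vocab.index("C"), vocab.eos_index)

    def test_chlorine_is_single_token(self):
        assert split_smiles("ClCCl") == ["Cl", "C", "Cl"]

    @pytest.mark.parametrize("smiles", FIXTURE_SMILES)
    def test_round_trip_on_corpus(self, smiles):
        vocab = build_vocab(FIXTURE_SMILES, ReprKind.SMILES)
        assert detokenize(tokenize(smiles, vocab), vocab) == smiles

    def test_selfies_vocab_round_trip(self):
        corpus = [smiles_to_selfies(s) for s in FIXTURE_SMILES]
        vocab = build_vocab(corpus, ReprKind.SELFIES)
        for selfies in corpus:
            assert detokenize(tokenize(selfies, vocab), vocab) == selfies

    def test_oov_names_offending_span(self):
        vocab = build_vocab(["CC"], ReprKind.SMILES)
        with pytest.raises(TokenizationError, match="Br"):
            tokenize("CBrC", vocab)

    def test_untokenizable_smiles_names_span(self):
        with pytest.raises(TokenizationError, match="position"):
            split_smiles("C!C")

    def test_exactly_one_eos_at_last_position(self):
        vocab = build_vocab(["CCO"], ReprKind.SMILES)
        seq = tokenize("CCO", vocab).padded(10, vocab.pad_index)
        eos_positions = [i for i, t in enumerate(seq.ids)
                         if t == vocab.eos_index]
        assert eos_positions == [len(seq) - seq.pad_length - 1]

    def test_vocab_save_load(self, tmp_path):
        vocab = build_vocab(FIXTURE_SMILES, ReprKind.SMILES)
        vocab.save(tmp_path / "vocab.json")
        loaded = type(vocab).load(tmp_path / "vocab.json")
        assert loaded.token_to_index == vocab.token_to_index
        assert loaded.repr_kind == vocab.repr_kind

    def test_specials_distinct_and_dense(self):
        vocab = build_vocab(["[C][O]"], ReprKind.SELFIES)
        assert len({vocab.pad_index, vocab.bos_index, vocab.eos_index}) == 3
        assert sorted(vocab.token_to_index.values()) == list(range(len(vocab)))
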