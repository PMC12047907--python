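"""Shared fixtures: molecule lists, scrambled SMILES, a trained toy assembly."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem

from textmol.nn import ModelAssembly, ModelConfig
from textmol.synthetic import make_dataset, training_pairs
from textmol.tokenizer import build_vocab
from textmol.training import TrainConfig, pretrain_decoder, train_adapter

#: 24 drug-like small molecules within the codec's encodable subset
FIXTURE_SMILES = [
    "Cc1ccc(O)cc1",
    "CCO",
    "CC(=O)O",
    "c1ccccc1",
    "C1CCCCC1",
    "CC(C)CC1=CC=C(C=C1)C(C)C(=O)O",
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",
    "ClCCCl",
    "O=C(O)c1ccccc1O",
    "N#Cc1ccc(Br)cc1",
    "C1CCNC1",
    "CC(C)(C)O",
    "c1ccc2ccccc2c1",
    "FC(F)(F)c1ccccc1",
    "CC#CC",
    "O=S(=O)(O)O",
    "CCCCCCCC",
    "S=C=S",
    "OCC1OC(O)C(O)C(O)C1O",
    "CC(N)C(=O)O",
    "O=C1CCCCC1",
    "Cn1cnc2ccccc21",
    "CSC",
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",
]


def scrambled_variants(smiles: str, n: int, seed: int) -> list[str]:
    """Equivalent SMILES strings with permuted atom numbering."""
    mol = Chem.MolFromSmiles(smiles)
    rng = np.random.default_rng(seed)
    variants = []
    for _ in range(n):
        order = rng.permutation(mol.GetNumAtoms()).tolist()
        renumbered = Chem.RenumberAtoms(mol, order)
        variants.append(Chem.MolToSmiles(renumbered, canonical=False))
    return variants


@pytest.fixture(scope="session")
def fixture_smiles() -> list[str]:
    return list(FIXTURE_SMILES)


@pytest.fixture(scope="session")
def toy_assembly() -> ModelAssembly:
    """Small assembly trained on 250 synthetic pairs (SELFIES targets)."""
    table, _ = make_dataset(250, seed=7)
    rows = training_pairs(table, "selfies")
    molecules = [m for _, m in rows]
    texts = [t for t, _ in rows]
    config = ModelConfig(d_text=32, d_mol=48, decoder_layers=2,
                         decoder_heads=4, text_layers=1, max_len=80,
                         repr_kind="selfies")
    assembly = ModelAssembly(config, build_vocab(molecules, "selfies"),
                             build_vocab(texts, "text", with_unk=True),
                             seed=7)
    pretrain_decoder(molecules, assembly,
                     TrainConfig(steps=150, batch_size=48, warmup_steps=60,
                                 seed=8))
    train_adapter(rows, assembly,
                  TrainConfig(steps=150, batch_size=48, warmup_steps=60,
                              seed=9))
    return assembly
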