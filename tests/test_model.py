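"""Adapter cross-attention, decoder causality, freeze contracts."""

import numpy as np
import pytest

from textmol.autograd import Tensor
from textmol.nn import (CrossAttentionAdapter, ModelAssembly, ModelConfig,
                        TextEncoder)
from textmol.tokenizer import build_vocab
from textmol.training import Adam, TrainConfig, pad_batch, teacher_forcing_loss
from textmol.tokenizer import tokenize


def _tiny_assembly(seed=0, **overrides) -> ModelAssembly:
    config = ModelConfig(d_text=16, d_mol=24, decoder_layers=2,
                         decoder_heads=4, text_layers=1, max_len=32,
                         repr_kind="smiles", **overrides)
    mol_vocab = build_vocab(["CCO", "CCN", "c1ccccc1", "CC(=O)O"], "smiles")
    text_vocab = build_vocab(["an alcohol", "an amine", "a ring compound"],
                             "text", with_unk=True)
    return ModelAssembly(config, mol_vocab, text_vocab, seed=seed)


def brute_force_attention(mol_emb, keys, mask, scale):
    """Loop-based softmax oracle for the adapter's attention matrix."""
    b, n, _ = mol_emb.shape
    m = keys.shape[1]
    out = np.zeros((b, n, m))
    for batch in range(b):
        for i in range(n):
            scores = []
            for j in range(m):
                s = float(mol_emb[batch, i] @ keys[batch, j]) * scale
                scores.append(s if mask[batch, j] else -np.inf)
            scores = np.array(scores)
            scores -= scores.max()
            e = np.exp(scores)
            out[batch, i] = e / e.sum()
    return out


class TestAdapterAttention:
    def test_matches_loop_oracle_on_random_shapes(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            d_text, d_mol = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            config = ModelConfig(d_text=d_text, d_mol=d_mol)
            adapter = CrossAttentionAdapter(config, rng)
            b = int(rng.integers(1, 3))
            m, n = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            text = Tensor(rng.normal(size=(b, m, d_text)))
            mol = Tensor(rng.normal(size=(b, n, d_mol)))
            mask = (rng.random((b, m)) < 0.8).astype(float)
            mask[:, 0] = 1.0  # at least one unmasked text position
            attn = adapter.attention(text, mol, mask).data
            keys = text.data @ adapter.key_proj.weight.data \
                + adapter.key_proj.bias.data
            oracle = brute_force_attention(mol.data, keys, mask,
                                           d_mol ** -0.5)
            assert np.allclose(attn, oracle, atol=1e-6)
            assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_text_position_gives_unit_weights(self):
        rng = np.random.default_rng(1)
        adapter = CrossAttentionAdapter(ModelConfig(d_text=8, d_mol=8), rng)
        text = Tensor(rng.normal(size=(1, 1, 8)))
        mol = Tensor(rng.normal(size=(1, 5, 8)))
        attn = adapter.attention(text, mol).data
        assert np.allclose(attn, 1.0)

    def test_identical_keys_give_uniform_rows(self):
        rng = np.random.default_rng(2)
        adapter = CrossAttentionAdapter(ModelConfig(d_text=8, d_mol=8), rng)
        one = rng.normal(size=8)
        text = Tensor(np.tile(one, (1, 4, 1)))
        mol = Tensor(rng.normal(size=(1, 3, 8)))
        attn = adapter.attention(text, mol).data
        assert np.allclose(attn, 0.25, atol=1e-12)

    def test_width_mismatch_raises(self):
        rng = np.random.default_rng(3)
        adapter = CrossAttentionAdapter(ModelConfig(d_text=8, d_mol=8), rng)
        with pytest.raises(ValueError, match="width"):
            adapter(Tensor(np.zeros((1, 2, 5))), Tensor(np.zeros((1, 2, 8))))
        with pytest.raises(ValueError, match="width"):
            adapter(Tensor(np.zeros((1, 2, 8))), Tensor(np.zeros((1, 2, 5))))


class TestZeroInitDelta:
    def test_conditional_equals_unconditional_at_init(self):
        assembly = _tiny_assembly(seed=4)
        rng = np.random.default_rng(5)
        text_ids, text_mask = pad_batch(
            [tokenize("an alcohol", assembly.text_vocab)],
            assembly.text_vocab.pad_index)
        for _ in range(20):
            length = int(rng.integers(1, 10))
            prefix = rng.integers(0, len(assembly.mol_vocab), size=(1, length))
            conditional = assembly.conditional_logits(text_ids, prefix,
                                                      text_mask).data
            unconditional = assembly.unconditional_logits(prefix).data
            assert np.allclose(conditional, unconditional, atol=1e-6)


class TestDecoder:
    def test_causality_suffix_perturbation(self):
        assembly = _tiny_assembly(seed=6)
        rng = np.random.default_rng(7)
        ids = rng.integers(0, len(assembly.mol_vocab), size=(1, 12))
        base = assembly.decoder_states(ids).data
        for k in (3, 7, 11):
            perturbed = ids.copy()
            perturbed[0, k] = (perturbed[0, k] + 1) % len(assembly.mol_vocab)
            states = assembly.decoder_states(perturbed).data
            assert np.allclose(states[0, :k], base[0, :k], atol=1e-12)
            assert not np.allclose(states[0, k:], base[0, k:])

    def test_logits_width_is_vocab_size(self):
        assembly = _tiny_assembly(seed=8)
        logits = assembly.unconditional_logits(np.zeros((1, 4), dtype=int))
        assert logits.shape == (1, 4, len(assembly.mol_vocab))

    def test_lm_head_zero_embedding_returns_bias(self):
        assembly = _tiny_assembly(seed=9)
        out = assembly.lm_head(Tensor(np.zeros((1, 1,
                                                assembly.config.d_mol))))
        assert np.allclose(out.data[0, 0], assembly.lm_head.bias.data)


class TestFreezeContract:
    def test_frozen_parts_bitwise_stable_under_training_step(self):
        assembly = _tiny_assembly(seed=10)
        frozen_before = {
            name: param.data.copy()
            for name, param in list(assembly.decoder.named_parameters("d."))
            + list(assembly.lm_head.named_parameters("h."))
        }
        adapter_before = [p.data.copy() for p in assembly.adapter.parameters()]

        text_ids, text_mask = pad_batch(
            [tokenize("an amine", assembly.text_vocab)],
            assembly.text_vocab.pad_index)
        ids, mask = pad_batch([tokenize("CCN", assembly.mol_vocab)],
                              assembly.mol_vocab.pad_index)
        optimizer = Adam(assembly.trainable_parameters(), TrainConfig())
        for _ in range(3):
            logits = assembly.conditional_logits(text_ids, ids[:, :-1],
                                                 text_mask)
            loss = teacher_forcing_loss(logits, ids[:, 1:], mask[:, 1:])
            loss.backward()
            optimizer.step(1e-2)
            optimizer.zero_grad()

        frozen_after = dict(
            list(assembly.decoder.named_parameters("d."))
            + list(assembly.lm_head.named_parameters("h.")))
        for name, before in frozen_before.items():
            assert np.array_equal(before, frozen_after[name].data), name
        changed = any(
            not np.array_equal(b, p.data)
            for b, p in zip(adapter_before, assembly.adapter.parameters()))
        assert changed


class TestTextEncoder:
    def test_deterministic_and_mask_length(self):
        assembly = _tiny_assembly(seed=11)
        ids, mask = pad_batch([tokenize("an alcohol", assembly.text_vocab)],
                              assembly.text_vocab.pad_index)
        a = assembly.encode_text(ids, mask).data
        b = assembly.encode_text(ids, mask).data
        assert np.array_equal(a, b)
        assert a.shape[1] == ids.shape[1]
        assert mask.sum() == len(tokenize("an alcohol", assembly.text_vocab))

    def test_different_texts_give_different_embeddings(self):
        assembly = _tiny_assembly(seed=12)
        first, _ = pad_batch([tokenize("an alcohol", assembly.text_vocab)],
                             assembly.text_vocab.pad_index)
        second, _ = pad_batch([tokenize("a ring compound",
                                        assembly.text_vocab)],
                              assembly.text_vocab.pad_index)
        a = assembly.encode_text(first).data
        b = assembly.encode_text(second).data
        assert a.shape != b.shape or not np.allclose(a, b)


class TestPersistence:
    def test_save_load_preserves_outputs(self, tmp_path):
        assembly = _tiny_assembly(seed=13)
        ids = np.array([[1, 4, 5, 2]])
        before = assembly.unconditional_logits(ids).data
        assembly.save(tmp_path / "model")
        loaded = ModelAssembly.load(tmp_path / "model")
        after = loaded.unconditional_logits(ids).data
        assert np.array_equal(before, after)
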