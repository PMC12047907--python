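"""Transformer building blocks and the adapter-linked model assembly.

The assembly mirrors the linked-model design for text-conditioned molecule
generation: a text encoder produces embeddings T = {t_1..t_m}; a GPT-style
causal molecule decoder produces last-layer token embeddings S = {s_1..s_n};
a cross-attention adapter projects T into the decoder's embedding width,
attends from molecule queries to the projected text (softmax over text
positions), and returns an updated S' that is fed to the decoder's own
language-model head.  The adapter's two residual sub-blocks (attention and
feed-forward) have zero-initialized output projections, so an untrained
adapter leaves the unconditional decoder distribution exactly unchanged.

Decoder weights and the LM head are frozen during adapter training; the text
encoder may be trainable or frozen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .autograd import Tensor, embedding, layer_norm, softmax
from .tokenizer import Vocabulary

__all__ = [
    "ModelConfig",
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "SelfAttention",
    "FeedForward",
    "TransformerBlock",
    "TextEncoder",
    "MoleculeDecoder",
    "CrossAttentionAdapter",
    "ModelAssembly",
]

NEG_INF = -1e9


@dataclass
class ModelConfig:
    """Widths and depths of the assembly.

    Defaults are desk-scale; a publication-scale decoder (256-dimensional
    embedding, 12 layers, 8 heads) is expressible by overriding ``d_mol``,
    ``decoder_layers`` and ``decoder_heads``.
    """

    d_text: int = 96
    d_mol: int = 128
    decoder_layers: int = 2
    decoder_heads: int = 4
    text_layers: int = 1
    text_heads: int = 4
    max_len: int = 96
    scaled_attention: bool = True
    freeze_decoder: bool = True
    freeze_text_encoder: bool = False
    repr_kind: str = "selfies"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, payload: str) -> "ModelConfig":
        return cls(**json.loads(payload))


class Module:
    """Parameter container with recursive traversal and freeze support."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def trainable_parameters(self) -> list[Tensor]:
        return [p for p in self.parameters() if p.requires_grad]

    def set_trainable(self, flag: bool) -> None:
        for p in self.parameters():
            p.requires_grad = flag

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False):
        if zero_init:
            weight = np.zeros((d_in, d_out))
        else:
            weight = rng.normal(0.0, d_in ** -0.5, size=(d_in, d_out))
        self.weight = Tensor(weight, requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, d ** -0.5, size=(n, d)),
                             requires_grad=True)

    def __call__(self, indices: np.ndarray) -> Tensor:
        return embedding(self.weight, indices)


class LayerNorm(Module):
    def __init__(self, d: int):
        self.gain = Tensor(np.ones(d), requires_grad=True)
        self.bias = Tensor(np.zeros(d), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gain, self.bias)


def _split_heads(x: Tensor, heads: int) -> Tensor:
    b, n, d = x.shape
    return x.reshape(b, n, heads, d // heads).transpose(0, 2, 1, 3)


def _merge_heads(x: Tensor) -> Tensor:
    b, h, n, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, n, h * dh)


def _causal_bias(n: int) -> np.ndarray:
    return np.triu(np.full((n, n), NEG_INF), k=1)


def _key_mask_bias(key_mask: np.ndarray) -> np.ndarray:
    # key_mask: (B, m) with 1 = real token, 0 = pad
    return (1.0 - np.asarray(key_mask, dtype=np.float64))[:, None, None, :] * NEG_INF


class SelfAttention(Module):
    def __init__(self, d: int, heads: int, causal: bool,
                 rng: np.random.Generator):
        if d % heads:
            raise ValueError("width must be divisible by head count")
        self.heads = heads
        self.causal = causal
        self.q = Linear(d, d, rng)
        self.k = Linear(d, d, rng)
        self.v = Linear(d, d, rng)
        self.out = Linear(d, d, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
        n, d = x.shape[-2], x.shape[-1]
        q = _split_heads(self.q(x), self.heads)
        k = _split_heads(self.k(x), self.heads)
        v = _split_heads(self.v(x), self.heads)
        scores = (q @ k.swapaxes(-1, -2)) * ((d // self.heads) ** -0.5)
        if self.causal:
            scores = scores + _causal_bias(n)
        if key_mask is not None:
            scores = scores + _key_mask_bias(key_mask)
        attn = softmax(scores, axis=-1)
        return self.out(_merge_heads(attn @ v))


class FeedForward(Module):
    def __init__(self, d: int, rng: np.random.Generator, mult: int = 4,
                 zero_init_out: bool = False):
        self.up = Linear(d, mult * d, rng)
        self.down = Linear(mult * d, d, rng, zero_init=zero_init_out)

    def __call__(self, x: Tensor) -> Tensor:
        return self.down(self.up(x).relu())


class TransformerBlock(Module):
    """Pre-norm residual block: x + Attn(LN(x)); x + FFN(LN(x))."""

    def __init__(self, d: int, heads: int, causal: bool,
                 rng: np.random.Generator):
        self.ln1 = LayerNorm(d)
        self.attn = SelfAttention(d, heads, causal, rng)
        self.ln2 = LayerNorm(d)
        self.ffn = FeedForward(d, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
        x = x + self.attn(self.ln1(x), key_mask)
        return x + self.ffn(self.ln2(x))


class TextEncoder(Module):
    """Token + position embeddings with bidirectional transformer layers."""

    def __init__(self, vocab_size: int, config: ModelConfig,
                 rng: np.random.Generator):
        self.tok = Embedding(vocab_size, config.d_text, rng)
        self.pos = Embedding(config.max_len, config.d_text, rng)
        self.blocks = [
            TransformerBlock(config.d_text, config.text_heads, causal=False,
                             rng=rng)
            for _ in range(config.text_layers)
        ]
        self.ln = LayerNorm(config.d_text)

    def __call__(self, indices: np.ndarray,
                 mask: np.ndarray | None = None) -> Tensor:
        indices = np.atleast_2d(np.asarray(indices))
        m = indices.shape[1]
        x = self.tok(indices) + self.pos(np.arange(m))
        for block in self.blocks:
            x = block(x, key_mask=mask)
        return self.ln(x)


class MoleculeDecoder(Module):
    """GPT-style causal decoder over molecule tokens (last-layer states)."""

    def __init__(self, vocab_size: int, config: ModelConfig,
                 rng: np.random.Generator):
        self.tok = Embedding(vocab_size, config.d_mol, rng)
        self.pos = Embedding(config.max_len, config.d_mol, rng)
        self.blocks = [
            TransformerBlock(config.d_mol, config.decoder_heads, causal=True,
                             rng=rng)
            for _ in range(config.decoder_layers)
        ]
        self.ln = LayerNorm(config.d_mol)

    def __call__(self, indices: np.ndarray) -> Tensor:
        indices = np.atleast_2d(np.asarray(indices))
        n = indices.shape[1]
        x = self.tok(indices) + self.pos(np.arange(n))
        for block in self.blocks:
            x = block(x)
        return self.ln(x)


class CrossAttentionAdapter(Module):
    """Single-head cross-attention from molecule queries to projected text.

    T' = proj(T); a_{i,j} = softmax_j(s_i . t'_j / sqrt(d_mol));
    s'_i = s_i + W_o sum_j a_{i,j} v_j, followed by a pre-norm feed-forward
    residual.  ``W_o`` and the feed-forward output are zero-initialized.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.scaled = config.scaled_attention
        self.d_mol = config.d_mol
        self.key_proj = Linear(config.d_text, config.d_mol, rng)
        self.value_proj = Linear(config.d_text, config.d_mol, rng)
        self.out = Linear(config.d_mol, config.d_mol, rng, zero_init=True)
        self.ln = LayerNorm(config.d_mol)
        self.ffn = FeedForward(config.d_mol, rng, zero_init_out=True)

    def attention(self, text_emb: Tensor, mol_emb: Tensor,
                  text_mask: np.ndarray | None = None) -> Tensor:
        keys = self.key_proj(text_emb)
        scores = mol_emb @ keys.swapaxes(-1, -2)
        if self.scaled:
            scores = scores * (self.d_mol ** -0.5)
        if text_mask is not None:
            bias = (1.0 - np.asarray(text_mask, float))[:, None, :] * NEG_INF
            scores = scores + bias
        return softmax(scores, axis=-1)

    def __call__(self, text_emb: Tensor, mol_emb: Tensor,
                 text_mask: np.ndarray | None = None,
                 return_attention: bool = False):
        if text_emb.shape[-1] != self.key_proj.weight.shape[0]:
            raise ValueError(
                f"text width {text_emb.shape[-1]} does not match adapter "
                f"input width {self.key_proj.weight.shape[0]}"
            )
        if mol_emb.shape[-1] != self.d_mol:
            raise ValueError(
                f"molecule width {mol_emb.shape[-1]} does not match adapter "
                f"width {self.d_mol}"
            )
        attn = self.attention(text_emb, mol_emb, text_mask)
        values = self.value_proj(text_emb)
        updated = mol_emb + self.out(attn @ values)
        updated = updated + self.ffn(self.ln(updated))
        if return_attention:
            return updated, attn
        return updated


class ModelAssembly(Module):
    """Text encoder + frozen molecule decoder + adapter + shared LM head."""

    def __init__(self, config: ModelConfig, mol_vocab: Vocabulary,
                 text_vocab: Vocabulary, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.mol_vocab = mol_vocab
        self.text_vocab = text_vocab
        self.text_encoder = TextEncoder(len(text_vocab), config, rng)
        self.decoder = MoleculeDecoder(len(mol_vocab), config, rng)
        self.lm_head = Linear(config.d_mol, len(mol_vocab), rng)
        self.adapter = CrossAttentionAdapter(config, rng)
        self.apply_freeze_flags()

    # dataclass-ish attributes excluded from parameter traversal
    def named_parameters(self, prefix: str = ""):
        for name in ("text_encoder", "decoder", "lm_head", "adapter"):
            yield from getattr(self, name).named_parameters(f"{prefix}{name}.")

    def apply_freeze_flags(self) -> None:
        self.decoder.set_trainable(not self.config.freeze_decoder)
        self.lm_head.set_trainable(not self.config.freeze_decoder)
        self.text_encoder.set_trainable(not self.config.freeze_text_encoder)
        self.adapter.set_trainable(True)

    # -- forward passes -----------------------------------------------------
    def encode_text(self, text_idx: np.ndarray,
                    text_mask: np.ndarray | None = None) -> Tensor:
        return self.text_encoder(text_idx, text_mask)

    def decoder_states(self, mol_idx: np.ndarray) -> Tensor:
        return self.decoder(mol_idx)

    def unconditional_logits(self, mol_idx: np.ndarray) -> Tensor:
        return self.lm_head(self.decoder(mol_idx))

    def conditional_logits(self, text_idx: np.ndarray, mol_idx: np.ndarray,
                           text_mask: np.ndarray | None = None) -> Tensor:
        text_emb = self.encode_text(text_idx, text_mask)
        states = self.decoder(mol_idx)
        updated = self.adapter(text_emb, states, text_mask)
        return self.lm_head(updated)

    # -- persistence ---------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {name: p.data for name, p in self.named_parameters()}
        np.savez(directory / "weights.npz", **arrays)
        (directory / "config.json").write_text(self.config.to_json())
        self.mol_vocab.save(directory / "mol_vocab.json")
        self.text_vocab.save(directory / "text_vocab.json")

    @classmethod
    def load(cls, directory: str | Path) -> "ModelAssembly":
        directory = Path(directory)
        config = ModelConfig.from_json((directory / "config.json").read_text())
        mol_vocab = Vocabulary.load(directory / "mol_vocab.json")
        text_vocab = Vocabulary.load(directory / "text_vocab.json")
        assembly = cls(config, mol_vocab, text_vocab)
        with np.load(directory / "weights.npz") as payload:
            for name, param in assembly.named_parameters():
                param.data = payload[name].copy()
        assembly.apply_freeze_flags()
        return assembly
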