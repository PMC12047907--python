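"""Teacher-forcing training with Adam under the Noam warm-up schedule.

Two stages are provided:

``pretrain_decoder``
    unconditional next-token training of the molecule decoder and LM head on
    a molecule corpus (the stand-in for a pretrained chemical language
    model, which is afterwards frozen);
``train_adapter``
    teacher-forcing training of the adapter (and, unless frozen, the text
    encoder) on description/molecule pairs, with the decoder and LM head
    frozen.

The learning-rate schedule is the classic transformer warm-up:
``lr = d_model^-0.5 * min(step^-0.5, step * warmup^-1.5)``, linear during
warm-up and proportional to step^-0.5 afterwards, paired with Adam at common
defaults.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autograd import Tensor, cross_entropy
from .nn import ModelAssembly
from .tokenizer import TokenSequence, Vocabulary, tokenize

__all__ = [
    "TrainConfig",
    "TraceRow",
    "noam_lr",
    "teacher_forcing_loss",
    "Adam",
    "pad_batch",
    "pretrain_decoder",
    "train_adapter",
    "write_trace",
]


@dataclass
class TrainConfig:
    """Optimization settings.

    ``warmup_steps`` defaults to the published 4,000; short desk-scale runs
    should lower it together with ``steps`` so the schedule peaks inside the
    run.  ``lr_scale`` multiplies the Noam rate.
    """

    steps: int = 1000
    batch_size: int = 32
    warmup_steps: int = 4000
    lr_scale: float = 1.0
    seed: int = 0
    eval_every: int = 50
    patience: int | None = None
    beta1: float = 0.9
    beta2: float = 0.98
    eps: float = 1e-9

    def __post_init__(self) -> None:
        if self.warmup_steps < 1:
            raise ValueError("warmup_steps must be >= 1")


@dataclass
class TraceRow:
    step: int
    lr: float
    train_loss: float
    valid_loss: float = float("nan")


def noam_lr(step: int, warmup: int, d_model: int) -> float:
    """Noam rate: d_model^-0.5 * min(step^-0.5, step * warmup^-1.5)."""
    if step < 1:
        raise ValueError("step must be >= 1")
    return d_model ** -0.5 * min(step ** -0.5, step * warmup ** -1.5)


def teacher_forcing_loss(logits: Tensor, targets: np.ndarray,
                         pad_mask: np.ndarray) -> Tensor:
    """Mean cross-entropy where position i of ``logits`` predicts
    ``targets[i]`` (the next token); ``pad_mask`` zeroes padded positions."""
    targets = np.asarray(targets)
    if logits.shape[:-1] != targets.shape or targets.shape != np.asarray(
            pad_mask).shape:
        raise ValueError(
            f"shape mismatch: logits {logits.shape}, targets "
            f"{targets.shape}, mask {np.asarray(pad_mask).shape}"
        )
    return cross_entropy(logits, targets, pad_mask)


class Adam:
    """Adam over the trainable parameters only; frozen tensors untouched."""

    def __init__(self, params: list[Tensor], config: TrainConfig):
        self.params = [p for p in params if p.requires_grad]
        self.config = config
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        cfg = self.config
        self.t += 1
        correction1 = 1.0 - cfg.beta1 ** self.t
        correction2 = 1.0 - cfg.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= cfg.beta1
            m += (1.0 - cfg.beta1) * p.grad
            v *= cfg.beta2
            v += (1.0 - cfg.beta2) * np.square(p.grad)
            p.data -= lr * (m / correction1) / (
                np.sqrt(v / correction2) + cfg.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def pad_batch(seqs: list[TokenSequence], pad_index: int
              ) -> tuple[np.ndarray, np.ndarray]:
    """Pad to max length in the batch; returns (ids, mask) int/float arrays."""
    longest = max(len(s) for s in seqs)
    ids = np.full((len(seqs), longest), pad_index, dtype=np.int64)
    mask = np.zeros((len(seqs), longest), dtype=np.float64)
    for i, seq in enumerate(seqs):
        ids[i, :len(seq)] = seq.ids
        mask[i, :len(seq)] = 1.0
    return ids, mask


def _shift_for_next_token(ids: np.ndarray, mask: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(input, target, target_mask): position i predicts token i+1."""
    return ids[:, :-1], ids[:, 1:], mask[:, 1:]


def _batch_loss_unconditional(assembly: ModelAssembly, ids, mask) -> Tensor:
    inp, tgt, tmask = _shift_for_next_token(ids, mask)
    return teacher_forcing_loss(assembly.unconditional_logits(inp), tgt, tmask)


def _batch_loss_conditional(assembly: ModelAssembly, text_ids, text_mask,
                            ids, mask) -> Tensor:
    inp, tgt, tmask = _shift_for_next_token(ids, mask)
    logits = assembly.conditional_logits(text_ids, inp, text_mask)
    return teacher_forcing_loss(logits, tgt, tmask)


def _check_finite(loss: float, step: int) -> None:
    if not np.isfinite(loss):
        raise FloatingPointError(
            f"non-finite training loss {loss} at step {step}; aborting"
        )


def _run_loop(step_fn, eval_fn, optimizer: Adam, d_model: int,
              config: TrainConfig) -> list[TraceRow]:
    trace: list[TraceRow] = []
    best = np.inf
    since_best = 0
    for step in range(1, config.steps + 1):
        lr = config.lr_scale * noam_lr(step, config.warmup_steps, d_model)
        loss = step_fn(step)
        _check_finite(loss, step)
        optimizer.step(lr)
        optimizer.zero_grad()
        row = TraceRow(step, lr, loss)
        if eval_fn is not None and (step % config.eval_every == 0
                                    or step == config.steps):
            row.valid_loss = eval_fn()
            if config.patience is not None:
                if row.valid_loss < best - 1e-6:
                    best = row.valid_loss
                    since_best = 0
                else:
                    since_best += 1
                    if since_best > config.patience:
                        trace.append(row)
                        break
        trace.append(row)
    return trace


def _tokenize_corpus(strings: list[str], vocab: Vocabulary
                     ) -> list[TokenSequence]:
    return [tokenize(s, vocab) for s in strings]


def pretrain_decoder(molecules: list[str], assembly: ModelAssembly,
                     config: TrainConfig,
                     valid_molecules: list[str] | None = None
                     ) -> list[TraceRow]:
    """Unconditional next-token pretraining of decoder + LM head."""
    if not molecules:
        raise ValueError("empty training corpus")
    assembly.decoder.set_trainable(True)
    assembly.lm_head.set_trainable(True)
    seqs = _tokenize_corpus(molecules, assembly.mol_vocab)
    valid_seqs = (_tokenize_corpus(valid_molecules, assembly.mol_vocab)
                  if valid_molecules else None)
    rng = np.random.default_rng(config.seed)
    params = (assembly.decoder.trainable_parameters()
              + assembly.lm_head.trainable_parameters())
    optimizer = Adam(params, config)
    pad = assembly.mol_vocab.pad_index

    def step_fn(step: int) -> float:
        pick = rng.integers(0, len(seqs), size=min(config.batch_size,
                                                   len(seqs)))
        ids, mask = pad_batch([seqs[i] for i in pick], pad)
        loss = _batch_loss_unconditional(assembly, ids, mask)
        loss.backward()
        return float(loss.data)

    def eval_fn() -> float:
        ids, mask = pad_batch(valid_seqs, pad)
        return float(_batch_loss_unconditional(assembly, ids, mask).data)

    trace = _run_loop(step_fn, eval_fn if valid_seqs else None, optimizer,
                      assembly.config.d_mol, config)
    # the pretrained decoder now plays the role of the frozen molecule model
    assembly.apply_freeze_flags()
    return trace


def train_adapter(pairs: list[tuple[str, str]], assembly: ModelAssembly,
                  config: TrainConfig,
                  valid_pairs: list[tuple[str, str]] | None = None
                  ) -> list[TraceRow]:
    """Teacher-forcing training of adapter (+ text encoder unless frozen).

    ``pairs`` holds (description text, molecule string in the assembly's
    representation).  Decoder and LM head stay frozen per the assembly's
    freeze flags.
    """
    if not pairs:
        raise ValueError("empty training table")
    assembly.apply_freeze_flags()

    def prep(table):
        texts = [tokenize(t, assembly.text_vocab) for t, _ in table]
        mols = [tokenize(m, assembly.mol_vocab) for _, m in table]
        return texts, mols

    texts, mols = prep(pairs)
    valid = prep(valid_pairs) if valid_pairs else None
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(assembly.trainable_parameters(), config)
    mol_pad = assembly.mol_vocab.pad_index
    text_pad = assembly.text_vocab.pad_index

    def batch_loss(text_seqs, mol_seqs) -> Tensor:
        text_ids, text_mask = pad_batch(text_seqs, text_pad)
        ids, mask = pad_batch(mol_seqs, mol_pad)
        return _batch_loss_conditional(assembly, text_ids, text_mask, ids,
                                       mask)

    def step_fn(step: int) -> float:
        pick = rng.integers(0, len(texts), size=min(config.batch_size,
                                                    len(texts)))
        loss = batch_loss([texts[i] for i in pick], [mols[i] for i in pick])
        loss.backward()
        return float(loss.data)

    def eval_fn() -> float:
        return float(batch_loss(*valid).data)

    return _run_loop(step_fn, eval_fn if valid else None, optimizer,
                     assembly.config.d_mol, config)


def write_trace(path: str | Path, trace: list[TraceRow]) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["step", "lr", "train_loss", "valid_loss"])
        for row in trace:
            writer.writerow([row.step, f"{row.lr:.8g}",
                             f"{row.train_loss:.8g}",
                             f"{row.valid_loss:.8g}"])
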