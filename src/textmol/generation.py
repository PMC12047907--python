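"""Autoregressive sampling and the temperature-escalation protocol.

Generation starts from BOS and stops at EOS or ``max_length``; greedy mode
takes the argmax (ties to the lowest index) and multinomial mode draws from
``softmax(logits / temperature)``.  The escalation protocol draws a first
sample at temperature 1.0, then escalates from 1.5 in fixed increments up to
a ceiling (default 4.5), drawing up to a per-temperature cap with varying
seeds (base seed + draw index), deduplicating by canonical SMILES and
applying the four post-generation filters until the target number of
successful molecules is collected or the ceiling is exhausted.

SELFIES assemblies report decoded SMILES; samples that fail to parse still
consume a sampling iteration and are logged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Callable

import numpy as np

from .chem import ReprKind, parse_molecule
from .evaluation import postgen_filter
from .nn import ModelAssembly
from .tokenizer import tokenize
from .training import pad_batch

__all__ = [
    "SamplingConfig",
    "EscalationConfig",
    "SampleRecord",
    "GenerationLog",
    "sample_next",
    "generate",
    "generate_batch",
    "generate_unconditional_batch",
    "sample_until_unique",
    "collect_until_target",
]

VERDICTS = ("success", "duplicate", "invalid", "natural_language", "salt",
            "single_element")


@dataclass(frozen=True)
class SamplingConfig:
    mode: str = "multinomial"  # or "greedy"
    temperature: float = 1.0
    seed: int = 42
    max_length: int = 48

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.mode not in ("greedy", "multinomial"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")


@dataclass(frozen=True)
class EscalationConfig:
    """Escalation sampling protocol parameters."""

    first_temperature: float = 1.0
    start_temperature: float = 1.5
    increment: float = 0.5
    ceiling: float = 4.5
    per_temperature_cap: int = 1000
    target: int = 100
    base_seed: int = 42
    max_length: int = 48

    def __post_init__(self) -> None:
        if self.ceiling < self.start_temperature:
            raise ValueError("ceiling must be >= start temperature")
        if self.per_temperature_cap < 1 or self.target < 1:
            raise ValueError("cap and target must be >= 1")
        if self.increment <= 0:
            raise ValueError("increment must be positive")


def sample_next(logits: np.ndarray, config: SamplingConfig,
                rng: np.random.Generator) -> int:
    """Next-token draw from raw logits (greedy argmax or multinomial)."""
    logits = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    if config.mode == "greedy":
        return int(np.argmax(logits))
    scaled = logits / config.temperature
    scaled -= scaled.max()
    probs = np.exp(scaled)
    probs /= probs.sum()
    return int(rng.choice(len(probs), p=probs))


def _encode_texts(assembly: ModelAssembly, texts: list[str]
                  ) -> tuple[np.ndarray, np.ndarray]:
    seqs = [tokenize(t, assembly.text_vocab) for t in texts]
    return pad_batch(seqs, assembly.text_vocab.pad_index)


def _autoregress(assembly: ModelAssembly,
                 text_ids: np.ndarray | None,
                 text_mask: np.ndarray | None,
                 n_rows: int,
                 config: SamplingConfig,
                 seeds: list[int]) -> list[str]:
    """Batched sampling; each row owns its RNG, so results match the
    one-at-a-time protocol regardless of batch composition."""
    vocab = assembly.mol_vocab
    rngs = [np.random.default_rng(s) for s in seeds]
    context = np.full((n_rows, 1), vocab.bos_index, dtype=np.int64)
    finished = np.zeros(n_rows, dtype=bool)
    text_emb = None
    if text_ids is not None:
        text_emb = assembly.encode_text(text_ids, text_mask)
    while context.shape[1] <= config.max_length and not finished.all():
        states = assembly.decoder(context)
        if text_emb is not None:
            states = assembly.adapter(text_emb, states, text_mask)
        logits = assembly.lm_head(states).data[:, -1, :]
        column = np.full(n_rows, vocab.pad_index, dtype=np.int64)
        for row in range(n_rows):
            if finished[row]:
                continue
            token = sample_next(logits[row], config, rngs[row])
            column[row] = token
            if token == vocab.eos_index:
                finished[row] = True
        context = np.concatenate([context, column[:, None]], axis=1)
    outputs = []
    for row in range(n_rows):
        tokens = []
        for index in context[row, 1:]:
            if index in (vocab.eos_index, vocab.pad_index):
                break
            tokens.append(vocab.index_to_token[index])
        outputs.append("".join(tokens))
    return outputs


def generate(text: str | None, assembly: ModelAssembly,
             config: SamplingConfig = SamplingConfig()) -> str:
    """One molecule string for one description (None = unconditional)."""
    if text is None:
        return _autoregress(assembly, None, None, 1, config, [config.seed])[0]
    text_ids, text_mask = _encode_texts(assembly, [text])
    return _autoregress(assembly, text_ids, text_mask, 1, config,
                        [config.seed])[0]


def generate_batch(texts: list[str], assembly: ModelAssembly,
                   config: SamplingConfig = SamplingConfig(),
                   seeds: list[int] | None = None) -> list[str]:
    """One sample per description; row i uses seed ``config.seed + i`` unless
    explicit seeds are given."""
    if seeds is None:
        seeds = [config.seed + i for i in range(len(texts))]
    text_ids, text_mask = _encode_texts(assembly, texts)
    return _autoregress(assembly, text_ids, text_mask, len(texts), config,
                        seeds)


def generate_unconditional_batch(assembly: ModelAssembly, n: int,
                                 config: SamplingConfig = SamplingConfig(),
                                 seeds: list[int] | None = None) -> list[str]:
    """n samples from the bare decoder (no text conditioning)."""
    if seeds is None:
        seeds = [config.seed + i for i in range(n)]
    return _autoregress(assembly, None, None, n, config, seeds)


# --------------------------------------------------------------------------
# Escalation protocol
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleRecord:
    raw: str
    reported_smiles: str | None
    canonical: str | None
    temperature: float
    seed: int
    verdict: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass
class GenerationLog:
    """Per-sample record of an escalation sampling campaign."""

    records: list[SampleRecord] = field(default_factory=list)
    target: int = 0
    shortfall: bool = False

    def _count(self, verdict: str) -> int:
        return sum(r.verdict == verdict for r in self.records)

    @property
    def n_sample(self) -> int:
        return len(self.records)

    @property
    def n_duplicate(self) -> int:
        return self._count("duplicate")

    @property
    def n_invalid(self) -> int:
        return self._count("invalid")

    @property
    def n_natural_language(self) -> int:
        return self._count("natural_language")

    @property
    def n_salt(self) -> int:
        return self._count("salt")

    @property
    def n_single_element(self) -> int:
        return self._count("single_element")

    @property
    def n_success(self) -> int:
        return self._count("success")

    @property
    def n_unique(self) -> int:
        return self.n_sample - self.n_duplicate

    @property
    def successes(self) -> list[str]:
        return [r.canonical for r in self.records
                if r.verdict == "success" and r.canonical is not None]

    @property
    def unique_canonical(self) -> set[str]:
        return {r.canonical for r in self.records if r.canonical is not None}

    def to_jsonl(self, path: str | Path) -> None:
        header = json.dumps(
            {"target": self.target, "shortfall": self.shortfall},
            sort_keys=True)
        lines = [header] + [r.to_json() for r in self.records]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "GenerationLog":
        lines = Path(path).read_text().splitlines()
        meta = json.loads(lines[0])
        records = [SampleRecord(**json.loads(line)) for line in lines[1:]]
        return cls(records=records, target=meta["target"],
                   shortfall=meta["shortfall"])

    @classmethod
    def from_counts(cls, sample: int, duplicate: int, invalid: int, nl: int,
                    salts: int, se: int) -> "GenerationLog":
        """Synthesize a log with given per-verdict counts (for arithmetic on
        published campaign tables; records carry placeholder strings)."""
        successes = sample - duplicate - invalid - nl - salts - se
        if successes < 0:
            raise ValueError("counts exceed sample size")
        verdicts = (["duplicate"] * duplicate + ["invalid"] * invalid
                    + ["natural_language"] * nl + ["salt"] * salts
                    + ["single_element"] * se + ["success"] * successes)
        records = []
        for i, verdict in enumerate(verdicts):
            canonical = f"placeholder-{i}" if verdict in ("success",
                                                          "duplicate") else None
            records.append(SampleRecord(
                raw=f"sample-{i}", reported_smiles=canonical,
                canonical=canonical, temperature=float("nan"), seed=i,
                verdict=verdict))
        return cls(records=records, target=successes, shortfall=False)


def _classify(raw: str, repr_kind: ReprKind, seen: set[str]
              ) -> tuple[str | None, str | None, str]:
    """Returns (reported_smiles, canonical, verdict) for one raw sample."""
    if not raw:
        return None, None, "invalid"
    mol = parse_molecule(raw, repr_kind)
    if repr_kind is ReprKind.SELFIES:
        if not mol.is_valid:
            return None, None, "invalid"
        reported = mol.canonical_smiles
    else:
        reported = raw
    canonical = mol.canonical_smiles
    if canonical is not None and canonical in seen:
        return reported, canonical, "duplicate"
    verdict = postgen_filter(reported if reported is not None else raw)
    name = verdict.flag_name()
    return reported, canonical, name if name is not None else "success"


def collect_until_target(draw_fn: Callable[[float, int], str],
                         escalation: EscalationConfig,
                         repr_kind: ReprKind) -> GenerationLog:
    """Drive any draw function through the escalation protocol.

    ``draw_fn(temperature, seed)`` returns one raw molecule string.  Used by
    :func:`sample_until_unique` and directly testable with stub samplers.
    """
    log = GenerationLog(target=escalation.target)
    seen: set[str] = set()
    draw_index = 0

    def one_draw(temperature: float) -> None:
        nonlocal draw_index
        seed = escalation.base_seed + draw_index
        raw = draw_fn(temperature, seed)
        reported, canonical, verdict = _classify(raw, repr_kind, seen)
        if canonical is not None and verdict != "duplicate":
            seen.add(canonical)
        log.records.append(SampleRecord(
            raw=raw, reported_smiles=reported, canonical=canonical,
            temperature=temperature, seed=seed, verdict=verdict))
        draw_index += 1

    one_draw(escalation.first_temperature)
    temperature = escalation.start_temperature
    while (log.n_success < escalation.target
           and temperature <= escalation.ceiling + 1e-9):
        for _ in range(escalation.per_temperature_cap):
            if log.n_success >= escalation.target:
                break
            one_draw(temperature)
        temperature += escalation.increment
    log.shortfall = log.n_success < escalation.target
    return log


def sample_until_unique(text: str | None, assembly: ModelAssembly,
                        escalation: EscalationConfig = EscalationConfig()
                        ) -> GenerationLog:
    """Escalation sampling against a model assembly for one description."""
    repr_kind = ReprKind(assembly.config.repr_kind)

    def draw_fn(temperature: float, seed: int) -> str:
        config = SamplingConfig(mode="multinomial", temperature=temperature,
                                seed=seed, max_length=escalation.max_length)
        return generate(text, assembly, config)

    return collect_until_target(draw_fn, escalation, repr_kind)
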