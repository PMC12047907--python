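"""Vocabularies and tokenization for molecule strings and description text.

SMILES tokenization uses longest-match over a fixed inventory (two-letter
elements first, bracket atoms, ring/branch/bond symbols); SELFIES splits on
bracket tokens.  Text tokenization is lowercased whitespace splitting with
punctuation stripped.  Every vocabulary carries dense indices with the
special markers PAD, BOS, EOS (and UNK for text).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from .chem import ReprKind

__all__ = [
    "TokenizationError",
    "TokenSequence",
    "Vocabulary",
    "split_smiles",
    "split_text",
    "tokenize",
    "detokenize",
    "build_vocab",
    "read_smi",
    "write_smi",
]

PAD, BOS, EOS, UNK = "<pad>", "<bos>", "<eos>", "<unk>"

_SMILES_TOKEN_RE = re.compile(
    r"Cl|Br|Si|Se|\[[^\]]*\]|%\d{2}|[BCNOPSFIH]|[bcnops]|[=#\-+/\\().:~*$@]|\d"
)
_SELFIES_TOKEN_RE = re.compile(r"\[[^\[\]]*\]")
_TEXT_CLEAN_RE = re.compile(r"[^\w+\-]+")


class TokenizationError(ValueError):
    """Raised when a string cannot be covered by the token inventory."""


def split_smiles(raw: str) -> list[str]:
    """Longest-match SMILES segmentation; names the offending span on failure."""
    tokens: list[str] = []
    pos = 0
    while pos < len(raw):
        m = _SMILES_TOKEN_RE.match(raw, pos)
        if m is None:
            raise TokenizationError(
                f"untokenizable SMILES span {raw[pos:pos + 8]!r} "
                f"at position {pos} in {raw!r}"
            )
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


def split_selfies_tokens(raw: str) -> list[str]:
    tokens = _SELFIES_TOKEN_RE.findall(raw)
    if "".join(tokens) != raw:
        raise TokenizationError(f"untokenizable SELFIES string {raw!r}")
    return tokens


def split_text(text: str) -> list[str]:
    words = []
    for word in text.lower().split():
        cleaned = _TEXT_CLEAN_RE.sub("", word)
        if cleaned:
            words.append(cleaned)
    return words


def _split(raw: str, repr_kind: ReprKind | str) -> list[str]:
    kind = repr_kind if isinstance(repr_kind, str) else repr_kind.value
    if kind == "text":
        return split_text(raw)
    kind = ReprKind(kind)
    if kind is ReprKind.SMILES:
        return split_smiles(raw)
    return split_selfies_tokens(raw)


@dataclass(frozen=True)
class TokenSequence:
    """Vocabulary indices with BOS/EOS markers and trailing padding."""

    ids: tuple[int, ...]
    pad_length: int = 0

    def padded(self, total_length: int, pad_index: int) -> "TokenSequence":
        extra = total_length - len(self.ids)
        if extra < 0:
            raise ValueError("total_length shorter than sequence")
        return TokenSequence(self.ids + (pad_index,) * extra,
                             self.pad_length + extra)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class Vocabulary:
    """Dense token<->index map with special markers."""

    token_to_index: dict[str, int]
    repr_kind: str
    has_unk: bool = False
    index_to_token: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.token_to_index)
        if sorted(self.token_to_index.values()) != list(range(n)):
            raise ValueError("vocabulary indices must be dense in [0, |V|)")
        self.index_to_token = [""] * n
        for token, index in self.token_to_index.items():
            self.index_to_token[index] = token

    def __len__(self) -> int:
        return len(self.token_to_index)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    @property
    def pad_index(self) -> int:
        return self.token_to_index[PAD]

    @property
    def bos_index(self) -> int:
        return self.token_to_index[BOS]

    @property
    def eos_index(self) -> int:
        return self.token_to_index[EOS]

    def index(self, token: str) -> int:
        if token in self.token_to_index:
            return self.token_to_index[token]
        if self.has_unk:
            return self.token_to_index[UNK]
        raise TokenizationError(f"token {token!r} not in vocabulary")

    @classmethod
    def from_corpus(cls, corpus: list[str], repr_kind: ReprKind | str,
                    with_unk: bool = False) -> "Vocabulary":
        if not corpus:
            raise ValueError("cannot build a vocabulary from an empty corpus")
        kind = repr_kind if isinstance(repr_kind, str) else repr_kind.value
        seen: set[str] = set()
        for raw in corpus:
            seen.update(_split(raw, kind))
        specials = [PAD, BOS, EOS] + ([UNK] if with_unk else [])
        tokens = specials + sorted(seen - set(specials))
        return cls({tok: i for i, tok in enumerate(tokens)}, kind, with_unk)

    def save(self, path: str | Path) -> None:
        payload = {
            "repr_kind": self.repr_kind,
            "has_unk": self.has_unk,
            "token_to_index": self.token_to_index,
            "specials": {"pad": PAD, "bos": BOS, "eos": EOS},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        payload = json.loads(Path(path).read_text())
        return cls(payload["token_to_index"], payload["repr_kind"],
                   payload.get("has_unk", False))


def build_vocab(corpus: list[str], repr_kind: ReprKind | str,
                with_unk: bool = False) -> Vocabulary:
    """Vocabulary covering every token in ``corpus`` plus specials."""
    return Vocabulary.from_corpus(corpus, repr_kind, with_unk)


def tokenize(raw: str, vocab: Vocabulary) -> TokenSequence:
    """BOS + token indices + EOS; errors name the out-of-vocabulary span."""
    ids = [vocab.bos_index]
    ids.extend(vocab.index(tok) for tok in _split(raw, vocab.repr_kind))
    ids.append(vocab.eos_index)
    return TokenSequence(tuple(ids))


def detokenize(seq: TokenSequence, vocab: Vocabulary) -> str:
    """Invert :func:`tokenize`, dropping specials and stopping at EOS."""
    out: list[str] = []
    for index in seq.ids:
        if index == vocab.eos_index:
            break
        if index in (vocab.bos_index, vocab.pad_index):
            continue
        out.append(vocab.index_to_token[index])
    joiner = " " if vocab.repr_kind == "text" else ""
    return joiner.join(out)


def read_smi(path: str | Path) -> list[tuple[str, str | None]]:
    """Read a .smi file: one molecule per line, optional identifier."""
    rows: list[tuple[str, str | None]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        rows.append((parts[0], parts[1].strip() if len(parts) > 1 else None))
    return rows


def write_smi(path: str | Path, rows: list[tuple[str, str | None]]) -> None:
    lines = [s if ident is None else f"{s}\t{ident}" for s, ident in rows]
    Path(path).write_text("\n".join(lines) + "\n")
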