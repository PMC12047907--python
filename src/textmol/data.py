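"""Loading, curation, and splitting of paired description-molecule tables.

Curation follows a fixed order, each stage with a logged count:
validity -> strict word-count filter -> exact-duplicate collapse ->
one-to-many removal -> overlap removal against a reference table.  Word
counting splits on runs of whitespace with no punctuation stripping; the
word-count rule is strictly greater-than.  One-to-many detection and overlap
removal compare canonical SMILES, so equivalent atom orderings collide.
Descriptions mapping to several distinct molecules are removed entirely;
several descriptions of one molecule are retained.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import Molecule, ReprKind, parse_molecule

__all__ = [
    "DescriptionPair",
    "PairTable",
    "SchemaError",
    "CurationReport",
    "load_pairs",
    "save_pairs",
    "filter_by_word_count",
    "remove_one_to_many",
    "remove_overlap",
    "split",
    "curate",
    "CHEBI20_COLUMNS",
]

#: ChEBI-20 style layout: identifier, molecule, description
CHEBI20_COLUMNS = ("CID", "SMILES", "description")
DEFAULT_COLUMNS = ("id", "description", "smiles")


class SchemaError(ValueError):
    """Missing/duplicated columns or identifiers, or an empty table."""


@dataclass(frozen=True)
class DescriptionPair:
    id: str
    description: str
    molecule: Molecule

    def word_count(self) -> int:
        return len(self.description.split())


@dataclass
class PairTable:
    """Ordered description-molecule pairs with unique identifiers."""

    pairs: list[DescriptionPair]
    provenance: str = "unsplit"

    def __post_init__(self) -> None:
        counts = Counter(p.id for p in self.pairs)
        dupes = [i for i, c in counts.items() if c > 1]
        if dupes:
            raise SchemaError(f"duplicate identifiers: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def canonical_set(self) -> set[str]:
        return {p.molecule.canonical_smiles for p in self.pairs
                if p.molecule.canonical_smiles is not None}

    def to_frame(self, columns: tuple[str, str, str] = DEFAULT_COLUMNS
                 ) -> pd.DataFrame:
        id_col, desc_col, smi_col = columns
        return pd.DataFrame({
            id_col: [p.id for p in self.pairs],
            desc_col: [p.description for p in self.pairs],
            smi_col: [p.molecule.raw for p in self.pairs],
        })


@dataclass
class CurationReport:
    rows_in: int = 0
    dropped_invalid: int = 0
    dropped_short: int = 0
    dropped_duplicate: int = 0
    dropped_one_to_many: int = 0
    dropped_overlap: int = 0
    rows_out: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True)


def _column_order(preset: str | tuple[str, str, str]) -> tuple[str, str, str]:
    """(id, description, smiles) column names for a preset or explicit tuple."""
    if isinstance(preset, tuple):
        return preset
    if preset == "chebi20":
        return (CHEBI20_COLUMNS[0], CHEBI20_COLUMNS[2], CHEBI20_COLUMNS[1])
    if preset == "default":
        return DEFAULT_COLUMNS
    raise SchemaError(f"unknown format preset {preset!r}")


def load_pairs(path: str | Path,
               columns: str | tuple[str, str, str] = "default",
               sep: str | None = None,
               report: CurationReport | None = None) -> PairTable:
    """Read a delimited pairs table, dropping (and counting) invalid SMILES.

    ``columns`` is 'default' (id, description, smiles), 'chebi20'
    (CID, SMILES, description), or an explicit (id, description, smiles)
    name tuple.  ``sep=None`` sniffs tab vs comma from the header line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such pairs table: {path}")
    if sep is None:
        header = path.open().readline()
        sep = "\t" if "\t" in header else ","
    frame = pd.read_csv(path, sep=sep, dtype=str)
    if frame.empty:
        raise SchemaError(f"empty pairs table: {path}")
    id_col, desc_col, smi_col = _column_order(columns)
    missing = {id_col, desc_col, smi_col} - set(frame.columns)
    if missing:
        raise SchemaError(f"missing columns {sorted(missing)} in {path}")
    pairs: list[DescriptionPair] = []
    dropped = 0
    for _, row in frame.iterrows():
        raw = str(row[smi_col])
        try:
            mol = parse_molecule(raw, ReprKind.SMILES)
        except ValueError:
            mol = None
        if mol is None or not mol.is_valid:
            dropped += 1
            continue
        pairs.append(DescriptionPair(str(row[id_col]), str(row[desc_col]),
                                     mol))
    if report is not None:
        report.rows_in += len(frame)
        report.dropped_invalid += dropped
    return PairTable(pairs)


def save_pairs(table: PairTable, path: str | Path,
               columns: str | tuple[str, str, str] = "default",
               sep: str = "\t") -> None:
    id_col, desc_col, smi_col = _column_order(columns)
    frame = table.to_frame((id_col, desc_col, smi_col))
    if columns == "chebi20":
        frame = frame[[CHEBI20_COLUMNS[0], CHEBI20_COLUMNS[1],
                       CHEBI20_COLUMNS[2]]]
    frame.to_csv(path, sep=sep, index=False)


def filter_by_word_count(table: PairTable, min_words_exclusive: int
                         ) -> PairTable:
    """Retain rows with strictly more than ``min_words_exclusive`` words."""
    if min_words_exclusive < 0:
        raise ValueError("threshold must be >= 0")
    kept = [p for p in table if p.word_count() > min_words_exclusive]
    return PairTable(kept, table.provenance)


def _dedup_exact(table: PairTable) -> PairTable:
    """Collapse rows equal in (description, canonical molecule) to one."""
    seen: set[tuple[str, str | None]] = set()
    kept = []
    for p in table:
        key = (p.description, p.molecule.canonical_smiles)
        if key in seen:
            continue
        seen.add(key)
        kept.append(p)
    return PairTable(kept, table.provenance)


def remove_one_to_many(table: PairTable) -> PairTable:
    """Drop every row of any description paired with >1 distinct molecule.

    Comparison is by canonical SMILES; exact duplicate rows are collapsed
    first so trivial repetition does not delete valid data.
    """
    table = _dedup_exact(table)
    molecules_per_description: dict[str, set[str | None]] = {}
    for p in table:
        molecules_per_description.setdefault(p.description, set()).add(
            p.molecule.canonical_smiles)
    kept = [p for p in table
            if len(molecules_per_description[p.description]) == 1]
    return PairTable(kept, table.provenance)


def remove_overlap(table: PairTable, reference: PairTable) -> PairTable:
    """Drop rows whose canonical SMILES occurs in ``reference``."""
    blocked = reference.canonical_set()
    kept = [p for p in table if p.molecule.canonical_smiles not in blocked]
    return PairTable(kept, table.provenance)


def curate(table: PairTable, min_words_exclusive: int = 20,
           reference: PairTable | None = None,
           report: CurationReport | None = None) -> PairTable:
    """Full curation pipeline with per-stage logged counts."""
    if report is None:
        report = CurationReport()
    report.rows_in = report.rows_in or len(table)

    valid = PairTable([p for p in table if p.molecule.is_valid],
                      table.provenance)
    report.dropped_invalid += len(table) - len(valid)

    worded = filter_by_word_count(valid, min_words_exclusive)
    report.dropped_short = len(valid) - len(worded)

    deduped = _dedup_exact(worded)
    report.dropped_duplicate = len(worded) - len(deduped)

    one_to_one = remove_one_to_many(deduped)
    report.dropped_one_to_many = len(deduped) - len(one_to_one)

    if reference is not None:
        final = remove_overlap(one_to_one, reference)
        report.dropped_overlap = len(one_to_one) - len(final)
    else:
        final = one_to_one
    report.rows_out = len(final)
    return final


def split(table: PairTable,
          fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
          seed: int = 0) -> tuple[PairTable, PairTable, PairTable]:
    """Seeded disjoint train/valid/test split with sizes within rounding."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(table)
    order = np.random.default_rng(seed).permutation(n)
    cut1 = round(fractions[0] * n)
    cut2 = round((fractions[0] + fractions[1]) * n)
    groups = (order[:cut1], order[cut1:cut2], order[cut2:])
    names = ("train", "valid", "test")
    return tuple(
        PairTable([table.pairs[i] for i in sorted(idx)], name)
        for idx, name in zip(groups, names)
    )
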