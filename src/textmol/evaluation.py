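"""Metrics, post-generation filters, Table-style statistics, consensus ranks.

Similarity metrics compare generated molecules against references by exact
canonical-SMILES match and by Tanimoto similarity of MACCS keys (166 bits),
RDKit path-based fingerprints, and Morgan fingerprints (radius 2, 2048 bits).
Fingerprint means are computed over the *valid* generated molecules only, so
a method that emits more hard-to-generate valid molecules can see lower mean
similarity (the similarity/validity trade-off).

The four post-generation filters reject strings that (1) cannot be parsed,
(2) mix natural language with chemical notation, (3) contain salt/multiple
fragments, or (4) consist of a single heavy-atom element; a generation is a
success only if it survives all four unchanged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .chem import Molecule, ReprKind, parse_molecule
from .tokenizer import TokenizationError, split_smiles

__all__ = [
    "MetricReport",
    "FilterVerdict",
    "GenerationStats",
    "exact_match",
    "exact_rate",
    "fingerprint",
    "tanimoto",
    "similarity_report",
    "postgen_filter",
    "generation_stats",
    "exponential_consensus_rank",
]

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
_RDK = rdFingerprintGenerator.GetRDKitFPGenerator()


# --------------------------------------------------------------------------
# Similarity metrics
# --------------------------------------------------------------------------

def _as_molecule(mol: Molecule | str) -> Molecule:
    if isinstance(mol, str):
        return parse_molecule(mol, ReprKind.SMILES)
    return mol


def exact_match(gen: Molecule | str, ref: Molecule | str) -> bool:
    """True iff both parse and share one canonical SMILES."""
    try:
        gen = _as_molecule(gen)
    except ValueError:
        return False
    ref = _as_molecule(ref)
    if not ref.is_valid:
        raise ValueError(f"reference molecule {ref.raw!r} is invalid")
    if not gen.is_valid:
        return False
    return gen.canonical_smiles == ref.canonical_smiles


def exact_rate(pairs: list[tuple[Molecule | str, Molecule | str]]) -> float:
    if not pairs:
        raise ValueError("empty pair list")
    return sum(exact_match(g, r) for g, r in pairs) / len(pairs)


def fingerprint(mol: Molecule | str, kind: str):
    """Binary substructure fingerprint: 'maccs', 'rdk', or 'morgan'."""
    mol = _as_molecule(mol)
    if not mol.is_valid:
        raise ValueError(f"cannot fingerprint invalid molecule {mol.raw!r}")
    rd = Chem.MolFromSmiles(mol.canonical_smiles)
    kind = kind.lower()
    if kind == "maccs":
        return MACCSkeys.GenMACCSKeys(rd)
    if kind == "rdk":
        return _RDK.GetFingerprint(rd)
    if kind == "morgan":
        return _MORGAN.GetFingerprint(rd)
    raise ValueError(f"unknown fingerprint kind {kind!r}")


def tanimoto(a, b) -> float:
    """|a & b| / |a | b| over bit sets or RDKit explicit bit vectors.

    The degenerate empty/empty pair scores 1.0 by convention (with a
    warning): two molecules with no set bits are indistinguishable.
    """
    if isinstance(a, (set, frozenset)) or isinstance(b, (set, frozenset)):
        a, b = set(a), set(b)
        union = a | b
        if not union:
            warnings.warn("Tanimoto of two empty bit sets; returning 1.0")
            return 1.0
        return len(a & b) / len(union)
    if a.GetNumOnBits() == 0 and b.GetNumOnBits() == 0:
        warnings.warn("Tanimoto of two empty fingerprints; returning 1.0")
        return 1.0
    return DataStructs.TanimotoSimilarity(a, b)


@dataclass
class MetricReport:
    """Exact match, mean fingerprint Tanimoto similarities, validity.

    Fingerprint means are over valid generated molecules only; they are NaN
    when no generated molecule is valid.
    """

    exact: float
    maccs_fts: float
    rdk_fts: float
    morgan_fts: float
    validity: float
    n_pairs: int
    n_valid: int

    def to_dict(self) -> dict:
        return {
            "exact": self.exact,
            "maccs_fts": self.maccs_fts,
            "rdk_fts": self.rdk_fts,
            "morgan_fts": self.morgan_fts,
            "validity": self.validity,
            "n_pairs": self.n_pairs,
            "n_valid": self.n_valid,
        }


def similarity_report(pairs: list[tuple[str, Molecule | str]],
                      gen_repr: ReprKind = ReprKind.SMILES) -> MetricReport:
    """Score generated strings against reference molecules.

    ``pairs`` holds (generated string, reference molecule).  Validity is the
    fraction of generated strings that parse; exact match is over all pairs;
    fingerprint means are over the valid generated molecules only.
    """
    if not pairs:
        raise ValueError("empty input")
    refs = [_as_molecule(r) for _, r in pairs]
    if not all(r.is_valid for r in refs):
        raise ValueError("all reference molecules must be valid")
    gens: list[Molecule | None] = []
    for raw, _ in pairs:
        if not raw:
            gens.append(None)
            continue
        mol = parse_molecule(raw, gen_repr)
        gens.append(mol if mol.is_valid else None)

    n_valid = sum(g is not None for g in gens)
    exact = sum(
        g is not None and g.canonical_smiles == r.canonical_smiles
        for g, r in zip(gens, refs)
    ) / len(pairs)
    sims = {"maccs": [], "rdk": [], "morgan": []}
    for g, r in zip(gens, refs):
        if g is None:
            continue
        for kind, store in sims.items():
            store.append(tanimoto(fingerprint(g, kind), fingerprint(r, kind)))

    def mean_or_nan(values: list[float]) -> float:
        return float(np.mean(values)) if values else float("nan")

    return MetricReport(
        exact=exact,
        maccs_fts=mean_or_nan(sims["maccs"]),
        rdk_fts=mean_or_nan(sims["rdk"]),
        morgan_fts=mean_or_nan(sims["morgan"]),
        validity=n_valid / len(pairs),
        n_pairs=len(pairs),
        n_valid=n_valid,
    )


# --------------------------------------------------------------------------
# Post-generation filters (permeability-style)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterVerdict:
    """Outcome of the four post-generation filters."""

    invalid: bool = False
    natural_language: bool = False
    salt: bool = False
    single_element: bool = False

    @property
    def success(self) -> bool:
        return not (self.invalid or self.natural_language or self.salt
                    or self.single_element)

    def flag_name(self) -> str | None:
        for name in ("natural_language", "invalid", "salt", "single_element"):
            if getattr(self, name):
                return name
        return None


def postgen_filter(raw: str) -> FilterVerdict:
    """Classify a generated SMILES string against the four filters.

    natural-language: whitespace or spans outside the molecular-string
    alphabet; invalid: untokenizable by RDKit; salt: multiple '.'-separated
    fragments (only the largest would be retained, and any removal fails the
    molecule); single-element: every heavy atom shares one element.
    """
    if not raw:
        return FilterVerdict(invalid=True)
    if any(c.isspace() for c in raw):
        return FilterVerdict(natural_language=True)
    try:
        split_smiles(raw)
    except TokenizationError:
        return FilterVerdict(natural_language=True)
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        return FilterVerdict(invalid=True)
    if len(Chem.GetMolFrags(mol)) > 1:
        return FilterVerdict(salt=True)
    elements = {atom.GetAtomicNum() for atom in mol.GetAtoms()
                if atom.GetAtomicNum() != 1}
    if len(elements) <= 1:
        return FilterVerdict(single_element=True)
    return FilterVerdict()


# --------------------------------------------------------------------------
# Generation-log statistics (Table-style row)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenerationStats:
    """Counts and success rate for one generation campaign.

    unique = sample - duplicate; unique = successes + invalid + nl + salts
    + se; success_rate = 100 * successes / unique, one decimal.
    """

    sample: int
    duplicate: int
    invalid: int
    nl: int
    salts: int
    se: int

    def __post_init__(self) -> None:
        if self.sample <= 0:
            raise ValueError("sample count must be positive")
        if self.successes < 0:
            raise ValueError("filter counts exceed unique count")

    @property
    def unique(self) -> int:
        return self.sample - self.duplicate

    @property
    def successes(self) -> int:
        return self.unique - self.invalid - self.nl - self.salts - self.se

    @property
    def success_rate(self) -> float:
        return round(100.0 * self.successes / self.unique, 1)

    def to_dict(self) -> dict:
        return {
            "sample": self.sample, "duplicate": self.duplicate,
            "unique": self.unique, "invalid": self.invalid, "nl": self.nl,
            "salts": self.salts, "se": self.se, "successes": self.successes,
            "success_rate": self.success_rate,
        }


def generation_stats(log) -> GenerationStats:
    """Table-style row from a GenerationLog (duck-typed on its counts)."""
    return GenerationStats(
        sample=log.n_sample, duplicate=log.n_duplicate, invalid=log.n_invalid,
        nl=log.n_natural_language, salts=log.n_salt,
        se=log.n_single_element,
    )


# --------------------------------------------------------------------------
# Exponential consensus ranking
# --------------------------------------------------------------------------

def exponential_consensus_rank(rank_lists: list[dict[str, int]],
                               sigma: float | None = None) -> dict[str, float]:
    """Aggregate per-scorer 1-based ranks into consensus scores.

    score(mol) = sum over scorers of (1/sigma) * exp(-rank/sigma); higher is
    better.  ``sigma`` defaults to 5% of the list length.
    """
    if not rank_lists:
        raise ValueError("no rank lists given")
    keys = set(rank_lists[0])
    for ranks in rank_lists[1:]:
        if set(ranks) != keys:
            raise ValueError("scorers rank different molecule sets")
    if sigma is None:
        sigma = max(1.0, 0.05 * len(keys))
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    scores = {key: 0.0 for key in keys}
    for ranks in rank_lists:
        for key, rank in ranks.items():
            if rank < 1:
                raise ValueError("ranks must be 1-based")
            scores[key] += math.exp(-rank / sigma) / sigma
    return scores
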