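"""Molecule string handling: parsing, validity, canonicalization, conversion.

Validity here is purely syntactic parseability plus RDKit's elementary
valence sanity; no 3D or physical plausibility check is made.  SELFIES input
is decoded to SMILES before validation, so a token stream that derives zero
atoms (e.g. one starting with an end-of-sequence marker) is invalid.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from rdkit import Chem, RDLogger

from . import selfies_codec

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ReprKind",
    "Molecule",
    "MoleculeError",
    "ConversionError",
    "parse_molecule",
    "canonicalize",
    "canonical_smiles_or_none",
    "strip_stereo",
    "smiles_to_selfies",
    "selfies_to_smiles",
]


class MoleculeError(ValueError):
    """Rejected or non-canonicalizable molecular input."""


class ConversionError(MoleculeError):
    """SMILES<->SELFIES conversion failure."""


class ReprKind(str, enum.Enum):
    SMILES = "smiles"
    SELFIES = "selfies"


@dataclass(frozen=True)
class Molecule:
    """A molecular string plus its parse outcome.

    ``is_valid`` is true exactly when ``canonical_smiles`` is present.
    """

    raw: str
    repr_kind: ReprKind
    canonical_smiles: str | None
    is_valid: bool

    def __post_init__(self) -> None:
        if self.is_valid != (self.canonical_smiles is not None):
            raise ValueError("is_valid must mirror canonical_smiles presence")


def canonical_smiles_or_none(smiles: str, strip_stereo: bool = False) -> str | None:
    """Canonical SMILES via RDKit, or None if the string does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    if strip_stereo:
        Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def parse_molecule(raw: str, repr_kind: ReprKind = ReprKind.SMILES) -> Molecule:
    """Parse a molecular string; validity reflects whether it parses.

    SELFIES is decoded to SMILES first.  Raises :class:`MoleculeError` for
    empty input; malformed strings yield an invalid :class:`Molecule`, not an
    exception.
    """
    if not raw:
        raise MoleculeError("empty molecular string")
    repr_kind = ReprKind(repr_kind)
    smiles = raw
    if repr_kind is ReprKind.SELFIES:
        try:
            smiles = selfies_codec.decode(raw)
        except selfies_codec.SelfiesError:
            smiles = ""
        if not smiles:
            return Molecule(raw, repr_kind, None, False)
    canonical = canonical_smiles_or_none(smiles)
    return Molecule(raw, repr_kind, canonical, canonical is not None)


def canonicalize(mol: Molecule | str, strip_stereo: bool = False) -> str:
    """Canonical SMILES of a valid molecule; raises for invalid input."""
    if isinstance(mol, str):
        mol = parse_molecule(mol, ReprKind.SMILES)
    if not mol.is_valid or mol.canonical_smiles is None:
        raise MoleculeError(f"cannot canonicalize invalid molecule {mol.raw!r}")
    if strip_stereo:
        out = canonical_smiles_or_none(mol.canonical_smiles, strip_stereo=True)
        assert out is not None
        return out
    return mol.canonical_smiles


def strip_stereo(smiles: str) -> str:
    """Remove stereochemical annotations, mirroring MOSES-style preprocessing."""
    out = canonical_smiles_or_none(smiles, strip_stereo=True)
    if out is None:
        raise MoleculeError(f"cannot parse SMILES {smiles!r}")
    return out


def smiles_to_selfies(smiles: str) -> str:
    """Encode SMILES as SELFIES; round-trip preserves the canonical SMILES."""
    reference = canonical_smiles_or_none(smiles, strip_stereo=True)
    if reference is None:
        raise ConversionError(f"cannot parse SMILES {smiles!r}")
    try:
        selfies = selfies_codec.encode(smiles)
        back = selfies_codec.decode(selfies)
    except selfies_codec.SelfiesError as exc:
        raise ConversionError(str(exc)) from exc
    if canonical_smiles_or_none(back) != reference:
        raise ConversionError(
            f"round-trip mismatch encoding {smiles!r}"
        )  # pragma: no cover - guarded by codec tests
    return selfies


def selfies_to_smiles(selfies: str) -> str:
    """Decode a SELFIES token string to SMILES."""
    try:
        smiles = selfies_codec.decode(selfies)
    except selfies_codec.SelfiesError as exc:
        raise ConversionError(str(exc)) from exc
    if not smiles:
        raise ConversionError("SELFIES string derives no atoms")
    return smiles
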