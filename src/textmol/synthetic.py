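"""Seeded paired text<->molecule data with decidable structural properties.

Descriptions deterministically encode four checkable properties of the
paired molecule — heavy-atom count, ring presence, oxygen content, halogen
content — padded with distractor clauses past the 20-word curation rule, so
text conditioning can be evaluated exactly with no external dataset.
Molecules come from a small enumerated template family (carbon chains,
saturated 5/6-rings, benzene cores, with optional hydroxyl tails and
halogen substituents), so ``check_property`` is exact structure inspection,
not a heuristic.

``run_conditioning_experiment`` is the desk-scale surrogate for conditional
generation quality: pretrain a decoder on the grammar's molecules, freeze
it, train the adapter on description/molecule pairs, then compare the
property-match rate of text-conditioned samples against the unconditional
decoder baseline on held-out specifications.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem import Molecule, ReprKind, parse_molecule, smiles_to_selfies
from .data import DescriptionPair, PairTable
from .generation import (SamplingConfig, generate_batch,
                         generate_unconditional_batch)
from .nn import ModelAssembly, ModelConfig
from .tokenizer import build_vocab
from .training import TrainConfig, pretrain_decoder, train_adapter

__all__ = [
    "PropertySpec",
    "SyntheticError",
    "sample_spec",
    "realize_molecule",
    "render_description",
    "check_property",
    "make_dataset",
    "training_pairs",
    "property_recovery_eval",
    "run_conditioning_experiment",
    "EXPERIMENT_DEFAULTS",
]

_HALOGENS = {9, 17, 35, 53}
_MIN_HEAVY, _MAX_HEAVY = 3, 9


class SyntheticError(ValueError):
    """Unrealizable property specification."""


@dataclass(frozen=True)
class PropertySpec:
    """Target structural properties for one synthetic molecule."""

    heavy_atoms: tuple[int, int]  # inclusive range
    has_ring: bool
    has_oxygen: bool
    has_halogen: bool
    scaffold: str  # chain | ring5 | ring6 | aromatic6

    def __post_init__(self) -> None:
        lo, hi = self.heavy_atoms
        if lo > hi or lo < 1:
            raise SyntheticError(f"bad heavy-atom range {self.heavy_atoms}")
        extras = int(self.has_oxygen) + int(self.has_halogen)
        minimum = {"chain": 1, "ring5": 5, "ring6": 6,
                   "aromatic6": 6}.get(self.scaffold)
        if minimum is None:
            raise SyntheticError(f"unknown scaffold {self.scaffold!r}")
        if self.has_ring == (self.scaffold == "chain"):
            raise SyntheticError("scaffold contradicts has_ring")
        if hi < minimum + extras:
            raise SyntheticError(
                f"spec unrealizable: needs >= {minimum + extras} heavy atoms")


def sample_spec(rng: np.random.Generator) -> PropertySpec:
    """Draw one realizable specification."""
    has_ring = bool(rng.random() < 0.5)
    has_oxygen = bool(rng.random() < 0.5)
    has_halogen = bool(rng.random() < 0.35)
    extras = int(has_oxygen) + int(has_halogen)
    floor = max(_MIN_HEAVY, (5 if has_ring else 1) + extras)
    n = int(rng.integers(floor, _MAX_HEAVY + 1))
    if has_ring:
        options = ["ring5"]
        if n >= 6 + extras:
            options += ["ring6", "aromatic6"]
        scaffold = str(rng.choice(options))
    else:
        scaffold = "chain"
    return PropertySpec((n, n), has_ring, has_oxygen, has_halogen, scaffold)


def realize_molecule(spec: PropertySpec, rng: np.random.Generator) -> Molecule:
    """Construct a molecule satisfying ``spec`` from its template family."""
    lo, hi = spec.heavy_atoms
    n = int(rng.integers(lo, hi + 1))
    extras = int(spec.has_oxygen) + int(spec.has_halogen)
    halogen = str(rng.choice(["F", "Cl"])) if spec.has_halogen else ""
    if spec.scaffold == "chain":
        carbons = n - extras
        if carbons < 1:
            raise SyntheticError("chain needs at least one carbon")
        smiles = halogen + "C" * carbons + ("O" if spec.has_oxygen else "")
    elif spec.scaffold in ("ring5", "ring6"):
        ring = 5 if spec.scaffold == "ring5" else 6
        tail = n - ring - extras
        if tail < 0:
            raise SyntheticError("ring larger than heavy-atom budget")
        branches = []
        side = "C" * tail + ("O" if spec.has_oxygen else "")
        if side:
            branches.append(side)
        if halogen:
            branches.append(halogen)
        core = "".join(f"({b})" for b in branches)
        smiles = "C1" + core + "C" * (ring - 2) + "C1"
    else:  # aromatic6
        tail = n - 6 - extras
        if tail < 0:
            raise SyntheticError("aromatic core larger than budget")
        side = "C" * tail + ("O" if spec.has_oxygen else "")
        inner = f"({side})" if side else ""
        smiles = halogen + f"c1ccc{inner}cc1"
    mol = parse_molecule(smiles, ReprKind.SMILES)
    if not mol.is_valid or not check_property(mol, spec):
        raise SyntheticError(
            f"template failure for {spec} -> {smiles}")  # pragma: no cover
    return mol


_DISTRACTORS = (
    "This entry was recorded during an automated screening campaign and "
    "kept for benchmarking purposes.",
    "The sample was catalogued under standard laboratory conditions without "
    "further purification steps.",
    "Analysts flagged the record as routine and assigned it to the general "
    "compound registry.",
    "The measurement batch completed without anomalies and passed the usual "
    "registration checks.",
)


def render_description(spec: PropertySpec,
                       rng: np.random.Generator | None = None,
                       identifier: str | None = None) -> str:
    """Templated description (> 20 words) encoding the four properties.

    The optional registry-identifier clause makes each dataset row's text
    unique, so generated tables pass curation with zero drops by
    construction.
    """
    lo, hi = spec.heavy_atoms
    count_clause = (f"The molecule contains a total of {lo} heavy atoms."
                    if lo == hi else
                    f"The molecule contains between {lo} and {hi} heavy "
                    f"atoms.")
    ring_clause = ("It contains a ring system." if spec.has_ring
                   else "It is acyclic with no ring system.")
    oxygen_clause = ("At least one oxygen atom is present."
                     if spec.has_oxygen else "No oxygen atom is present.")
    halogen_clause = ("The structure carries a halogen substituent."
                      if spec.has_halogen
                      else "The structure is free of halogen substituents.")
    if rng is None:
        fillers = [_DISTRACTORS[0], _DISTRACTORS[1]]
    else:
        fillers = list(rng.choice(_DISTRACTORS, size=2, replace=False))
    clauses = [fillers[0], count_clause, ring_clause, oxygen_clause,
               halogen_clause, fillers[1]]
    if identifier is not None:
        clauses.append(f"Registry identifier {identifier} marks this record.")
    return " ".join(clauses)


def check_property(mol: Molecule | str, spec: PropertySpec) -> bool:
    """Exact structural check of ``mol`` against ``spec``."""
    if isinstance(mol, str):
        mol = parse_molecule(mol, ReprKind.SMILES)
    if not mol.is_valid:
        raise ValueError(f"cannot check properties of invalid {mol.raw!r}")
    rd = Chem.MolFromSmiles(mol.canonical_smiles)
    lo, hi = spec.heavy_atoms
    if not lo <= rd.GetNumHeavyAtoms() <= hi:
        return False
    if bool(rd.GetRingInfo().NumRings()) != spec.has_ring:
        return False
    atomic_numbers = {a.GetAtomicNum() for a in rd.GetAtoms()}
    if (8 in atomic_numbers) != spec.has_oxygen:
        return False
    if bool(atomic_numbers & _HALOGENS) != spec.has_halogen:
        return False
    return True


def make_dataset(n: int, seed: int) -> tuple[PairTable, list[PropertySpec]]:
    """Seeded dataset of n description/molecule pairs plus their specs."""
    rng = np.random.default_rng(seed)
    pairs = []
    specs = []
    for i in range(n):
        spec = sample_spec(rng)
        mol = realize_molecule(spec, rng)
        identifier = f"SYN{i:06d}"
        description = render_description(spec, rng, identifier=identifier)
        pairs.append(DescriptionPair(identifier, description, mol))
        specs.append(spec)
    return PairTable(pairs, "unsplit"), specs


def training_pairs(table: PairTable, repr_kind: ReprKind | str
                   ) -> list[tuple[str, str]]:
    """(description, molecule string) rows in the requested representation."""
    repr_kind = ReprKind(repr_kind)
    rows = []
    for pair in table:
        smiles = pair.molecule.canonical_smiles
        target = (smiles_to_selfies(smiles)
                  if repr_kind is ReprKind.SELFIES else smiles)
        rows.append((pair.description, target))
    return rows


# --------------------------------------------------------------------------
# Conditioning surrogate experiment
# --------------------------------------------------------------------------

#: desk-scale study conditions for the conditioning experiment
EXPERIMENT_DEFAULTS = {
    "n_train": 2000,
    "n_eval": 200,
    "model": dict(d_text=48, d_mol=64, decoder_layers=2, decoder_heads=4,
                  text_layers=1, text_heads=4, max_len=80,
                  repr_kind="selfies"),
    "pretrain": dict(steps=500, batch_size=64, warmup_steps=150),
    "adapter": dict(steps=700, batch_size=48, warmup_steps=200),
}


def property_recovery_eval(assembly: ModelAssembly,
                           specs: Sequence[PropertySpec],
                           seed: int) -> dict:
    """Conditional vs unconditional property-match rates on held-out specs.

    One multinomial sample (temperature 1.0) per description; the
    unconditional baseline draws the same number of samples from the bare
    decoder and scores them against the same specs.
    """
    repr_kind = ReprKind(assembly.config.repr_kind)
    descriptions = [render_description(spec, identifier=f"EVAL{i:06d}")
                    for i, spec in enumerate(specs)]
    config = SamplingConfig(mode="multinomial", temperature=1.0, seed=seed,
                            max_length=assembly.config.max_len - 1)

    def match_rate(outputs: list[str]) -> float:
        hits = 0
        for raw, spec in zip(outputs, specs):
            if not raw:
                continue
            mol = parse_molecule(raw, repr_kind)
            if mol.is_valid and check_property(mol, spec):
                hits += 1
        return hits / len(specs)

    conditional = generate_batch(descriptions, assembly, config)
    unconditional = generate_unconditional_batch(
        assembly, len(specs), SamplingConfig(
            mode="multinomial", temperature=1.0, seed=seed + len(specs),
            max_length=assembly.config.max_len - 1))
    return {
        "conditional_match_rate": match_rate(conditional),
        "unconditional_match_rate": match_rate(unconditional),
        "n_eval": len(specs),
    }


def run_conditioning_experiment(seed: int,
                                n_train: int | None = None,
                                n_eval: int | None = None,
                                overrides: dict | None = None) -> dict:
    """Full surrogate: data -> decoder pretraining -> adapter -> evaluation.

    Returns the two match rates plus the final training losses.  All
    randomness derives from ``seed``.
    """
    settings = {**EXPERIMENT_DEFAULTS, **(overrides or {})}
    n_train = n_train or settings["n_train"]
    n_eval = n_eval or settings["n_eval"]

    table, _ = make_dataset(n_train, seed)
    eval_rng = np.random.default_rng(seed + 500_000)
    eval_specs = [sample_spec(eval_rng) for _ in range(n_eval)]

    repr_kind = ReprKind(settings["model"]["repr_kind"])
    rows = training_pairs(table, repr_kind)
    molecules = [m for _, m in rows]
    texts = [t for t, _ in rows]

    config = ModelConfig(**settings["model"])
    mol_vocab = build_vocab(molecules, repr_kind)
    text_vocab = build_vocab(texts, "text", with_unk=True)
    assembly = ModelAssembly(config, mol_vocab, text_vocab, seed=seed)

    pretrain_trace = pretrain_decoder(
        molecules, assembly,
        TrainConfig(seed=seed + 1, **settings["pretrain"]))
    adapter_trace = train_adapter(
        rows, assembly, TrainConfig(seed=seed + 2, **settings["adapter"]))

    result = property_recovery_eval(assembly, eval_specs, seed + 3)
    result["pretrain_final_loss"] = pretrain_trace[-1].train_loss
    result["adapter_final_loss"] = adapter_trace[-1].train_loss
    result["gap"] = (result["conditional_match_rate"]
                     - result["unconditional_match_rate"])
    result["assembly"] = assembly
    return result
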