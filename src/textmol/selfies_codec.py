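"""Robust SELFIES-style molecular string codec.

SELFIES represents a molecule as a sequence of bracketed tokens whose
derivation rules guarantee that *any* sequence over the token alphabet decodes
to a syntactically valid molecule: bond orders are capped by the remaining
valence of the atoms involved, and branch/ring tokens that cannot be realized
are skipped.  This module implements both directions:

``encode``
    kekulizable, single-fragment, non-isotopic SMILES -> token string
    (stereochemistry is dropped; the codec does not carry it).
``decode``
    any token string over the alphabet -> SMILES, built atom-by-atom under
    valence caps and canonicalized with RDKit.

Token spelling and the 16-symbol index alphabet follow the common v2 dialect,
e.g. ``[C][C][=C][C][=C][Branch1][Branch1][C][=C][Ring1][=Branch1][O]``
decodes to 4-methylphenol.

Branch and ring payloads are length/offset integers encoded in base 16 using
the index alphabet; ``[BranchN]``/``[RingN]`` read N index symbols.  A branch
of Q+1 tokens attaches at the current atom; a ring token bonds the current
atom to the atom Q+1 positions earlier in derivation order.
"""

from __future__ import annotations

import re

from rdkit import Chem

__all__ = [
    "SelfiesError",
    "SelfiesDecodeError",
    "SelfiesEncodeError",
    "split_selfies",
    "encode",
    "decode",
]


class SelfiesError(ValueError):
    """Base error for codec failures."""


class SelfiesDecodeError(SelfiesError):
    """Raised for strings that are not sequences of known tokens."""


class SelfiesEncodeError(SelfiesError):
    """Raised for SMILES outside the encodable subset."""


# Index alphabet: position defines the digit value 0..15 used to read
# branch lengths and ring offsets.
INDEX_ALPHABET = (
    "[C]", "[Ring1]", "[Ring2]",
    "[Branch1]", "[=Branch1]", "[#Branch1]",
    "[Branch2]", "[=Branch2]", "[#Branch2]",
    "[O]", "[N]", "[=N]", "[=C]", "[#C]", "[S]", "[P]",
)
_INDEX_CODE = {tok: i for i, tok in enumerate(INDEX_ALPHABET)}

# Remaining-valence caps by (element, formal charge).  Deliberately
# conservative so that every decoded graph passes RDKit sanitization.
_VALENCE = {
    ("B", 0): 3,
    ("C", 0): 4, ("C", 1): 3, ("C", -1): 3,
    ("N", 0): 3, ("N", 1): 4, ("N", -1): 2,
    ("O", 0): 2, ("O", 1): 3, ("O", -1): 1,
    ("S", 0): 6, ("S", 1): 3, ("S", -1): 1,
    ("P", 0): 5, ("P", 1): 4,
    ("F", 0): 1, ("Cl", 0): 1, ("Br", 0): 1, ("I", 0): 1,
    ("H", 0): 1,
}

_BOND_ORDER = {"": 1, "=": 2, "#": 3}
_ORDER_CHAR = {1: "", 2: "=", 3: "#"}

_TOKEN_RE = re.compile(r"\[[^\[\]]*\]")
_ATOM_TOKEN_RE = re.compile(
    r"^\[([=#]?)([A-Z][a-z]?)(?:H(\d+))?(?:([+-])(\d+))?\]$"
)
_BRANCH_TOKEN_RE = re.compile(r"^\[([=#]?)Branch([123])\]$")
_RING_TOKEN_RE = re.compile(r"^\[([=#]?)Ring([123])\]$")

#: tokens that terminate derivation when encountered mid-stream
TERMINATORS = frozenset({"[EOS]"})
_NOOPS = frozenset({"[nop]"})


def split_selfies(selfies: str) -> list[str]:
    """Split a SELFIES string into bracket tokens, rejecting stray text."""
    tokens = _TOKEN_RE.findall(selfies)
    if "".join(tokens) != selfies:
        raise SelfiesDecodeError(
            f"string is not a sequence of bracket tokens: {selfies!r}"
        )
    return tokens


def _cap(element: str, charge: int, hcount: int | None) -> int:
    base = _VALENCE.get((element, charge))
    if base is None:
        base = 4
    if hcount:
        base -= hcount
    return max(base, 0)


def _parse_atom_token(token: str):
    m = _ATOM_TOKEN_RE.match(token)
    if m is None:
        return None
    bond, elem, hs, sign, digits = m.groups()
    if elem in ("Branch", "Ring"):  # unreachable, but keep the intent clear
        return None
    charge = 0
    if sign:
        charge = int(digits) * (1 if sign == "+" else -1)
    hcount = int(hs) if hs is not None else None
    return _BOND_ORDER[bond], elem, hcount, charge


class _Graph:
    """Growing molecular graph with per-atom remaining valence."""

    def __init__(self) -> None:
        self.atoms: list[tuple[str, int, int | None]] = []
        self.rem: list[int] = []
        self.bonds: dict[tuple[int, int], int] = {}

    def add_atom(self, elem: str, charge: int, hcount: int | None) -> int:
        self.atoms.append((elem, charge, hcount))
        self.rem.append(_cap(elem, charge, hcount))
        return len(self.atoms) - 1

    def add_bond(self, i: int, j: int, order: int) -> None:
        key = (min(i, j), max(i, j))
        self.bonds[key] = order
        self.rem[i] -= order
        self.rem[j] -= order

    def has_bond(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.bonds

    def to_mol(self) -> Chem.Mol | None:
        if not self.atoms:
            return None
        rw = Chem.RWMol()
        for elem, charge, hcount in self.atoms:
            atom = Chem.Atom(elem)
            atom.SetFormalCharge(charge)
            if hcount is not None:
                atom.SetNumExplicitHs(hcount)
                atom.SetNoImplicit(True)
            rw.AddAtom(atom)
        order_map = {
            1: Chem.BondType.SINGLE,
            2: Chem.BondType.DOUBLE,
            3: Chem.BondType.TRIPLE,
        }
        for (i, j), order in self.bonds.items():
            rw.AddBond(i, j, order_map[order])
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        return mol


def _read_index(tokens: list[str], pos: int, n_symbols: int) -> tuple[int, int]:
    """Read ``n_symbols`` index digits; unknown tokens count as 0."""
    value = 0
    for _ in range(n_symbols):
        if pos >= len(tokens):
            return value, pos
        value = value * 16 + _INDEX_CODE.get(tokens[pos], 0)
        pos += 1
    return value, pos


def _derive(tokens: list[str], graph: _Graph,
            attach: int | None, attach_avail: int) -> None:
    """Derive one token stream, attaching its first atom to ``attach``.

    ``attach_avail`` caps the order of the bond into this stream; the cap for
    chain continuation afterwards is tracked through ``graph.rem``.
    """
    prev = attach
    first = attach is not None
    first_avail = attach_avail
    pos = 0
    while pos < len(tokens):
        token = tokens[pos]
        if token in TERMINATORS:
            return
        if token in _NOOPS:
            pos += 1
            continue

        atom = _parse_atom_token(token)
        if atom is not None:
            order, elem, hcount, charge = atom
            cap = _cap(elem, charge, hcount)
            if prev is None:
                prev = graph.add_atom(elem, charge, hcount)
                pos += 1
                continue
            avail = first_avail if first else graph.rem[prev]
            if avail <= 0:
                return  # current attachment point is saturated
            if cap == 0:
                pos += 1
                continue
            order = min(order, avail, cap)
            new = graph.add_atom(elem, charge, hcount)
            graph.add_bond(prev, new, order)
            prev = new
            first = False
            pos += 1
            continue

        m = _BRANCH_TOKEN_RE.match(token)
        if m is not None:
            b1 = _BOND_ORDER[m.group(1)]
            n_symbols = int(m.group(2))
            if prev is None or first or graph.rem[prev] <= 1:
                pos += 1  # branch impossible here; skip the symbol only
                continue
            q, pos = _read_index(tokens, pos + 1, n_symbols)
            sub = tokens[pos:pos + q + 1]
            pos += q + 1
            _derive(tokens=sub, graph=graph, attach=prev,
                    attach_avail=min(b1, graph.rem[prev] - 1))
            continue

        m = _RING_TOKEN_RE.match(token)
        if m is not None:
            order = _BOND_ORDER[m.group(1)]
            n_symbols = int(m.group(2))
            if prev is None or first:
                pos += 1
                continue
            q, pos = _read_index(tokens, pos + 1, n_symbols)
            target = max(0, len(graph.atoms) - 1 - (q + 1))
            if target == prev or graph.has_bond(prev, target):
                continue
            order = min(order, graph.rem[prev], graph.rem[target])
            if order >= 1:
                graph.add_bond(prev, target, order)
            continue

        raise SelfiesDecodeError(f"unknown token {token!r}")


def decode(selfies: str) -> str:
    """Decode a token string to a canonical SMILES ('' for zero atoms)."""
    tokens = split_selfies(selfies)
    graph = _Graph()
    _derive(tokens, graph, attach=None, attach_avail=0)
    mol = graph.to_mol()
    if mol is None:
        return ""
    return Chem.MolToSmiles(mol)


# --------------------------------------------------------------------------
# Encoding
# --------------------------------------------------------------------------

_SMILES_WALK_RE = re.compile(
    r"Cl|Br|\[[^\]]+\]|%\d{2}|[BCNOPSFI]|[=#\-()]|\d"
)
_BRACKET_ATOM_RE = re.compile(
    r"^\[(\d+)?([A-Z][a-z]?|[a-z])(@{1,2})?(?:H(\d*))?([+-]+\d*|\++|-+)?\]$"
)


def _atom_selfies_token(order: int, elem: str, hcount: int | None,
                        charge: int) -> str:
    parts = [_ORDER_CHAR[order], elem]
    if hcount:
        parts.append(f"H{hcount}")
    if charge:
        parts.append(f"{'+' if charge > 0 else '-'}{abs(charge)}")
    return "[" + "".join(parts) + "]"


def _encode_index(value: int) -> tuple[str, list[str]]:
    """Return (symbol count suffix '1'/'2'/'3', index digit tokens)."""
    if value < 16:
        return "1", [INDEX_ALPHABET[value]]
    if value < 16 ** 2:
        return "2", [INDEX_ALPHABET[value // 16], INDEX_ALPHABET[value % 16]]
    if value < 16 ** 3:
        return "3", [
            INDEX_ALPHABET[value // 256],
            INDEX_ALPHABET[(value // 16) % 16],
            INDEX_ALPHABET[value % 16],
        ]
    raise SelfiesEncodeError(f"index {value} too large to encode")


def _parse_bracket_atom(token: str) -> tuple[str, int | None, int]:
    m = _BRACKET_ATOM_RE.match(token)
    if m is None:
        raise SelfiesEncodeError(f"unsupported bracket atom {token!r}")
    isotope, elem, chiral, hs, charge_s = m.groups()
    if isotope:
        raise SelfiesEncodeError(f"isotopes not supported: {token!r}")
    if elem.islower():
        raise SelfiesEncodeError(f"unexpected aromatic atom {token!r}")
    del chiral  # stereochemistry was removed before the walk
    if hs is None:
        hcount = 0  # bracket atoms carry an explicit (possibly zero) H count
    elif hs == "":
        hcount = 1
    else:
        hcount = int(hs)
    charge = 0
    if charge_s:
        if charge_s in ("+", "-"):
            charge = 1 if charge_s == "+" else -1
        elif set(charge_s) <= {"+"}:
            charge = len(charge_s)
        elif set(charge_s) <= {"-"}:
            charge = -len(charge_s)
        else:
            charge = int(charge_s)
    return elem, hcount, charge


class _Encoder:
    def __init__(self, smiles_tokens: list[str]) -> None:
        self.tokens = smiles_tokens
        self.pos = 0
        self.n_atoms = 0
        self.open_rings: dict[str, tuple[int, int]] = {}

    def _peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def encode_chain(self, at_top: bool) -> list[str]:
        out: list[str] = []
        pending_bond = 1
        while True:
            token = self._peek()
            if token is None:
                if not at_top:
                    raise SelfiesEncodeError("unbalanced parentheses")
                return out
            if token == ")":
                if at_top:
                    raise SelfiesEncodeError("unbalanced parentheses")
                return out
            self.pos += 1
            if token in ("=", "#"):
                pending_bond = {"=": 2, "#": 3}[token]
                continue
            if token == "-":
                pending_bond = 1
                continue
            if token == "(":
                sub = self.encode_chain(at_top=False)
                if self._peek() != ")":
                    raise SelfiesEncodeError("unbalanced parentheses")
                self.pos += 1
                if not sub:
                    continue
                first = _parse_atom_token(sub[0])
                if first is None:
                    raise SelfiesEncodeError("branch must start with an atom")
                n_suffix, digits = _encode_index(len(sub) - 1)
                out.append(f"[{_ORDER_CHAR[first[0]]}Branch{n_suffix}]")
                out.extend(digits)
                out.extend(sub)
                continue
            if token.isdigit() or token.startswith("%"):
                label = token.lstrip("%")
                if label in self.open_rings:
                    open_atom, open_bond = self.open_rings.pop(label)
                    order = max(pending_bond, open_bond)
                    offset = self.n_atoms - 1 - open_atom - 1
                    n_suffix, digits = _encode_index(offset)
                    out.append(f"[{_ORDER_CHAR[order]}Ring{n_suffix}]")
                    out.extend(digits)
                else:
                    self.open_rings[label] = (self.n_atoms - 1, pending_bond)
                pending_bond = 1
                continue
            # atom token
            if token.startswith("["):
                elem, hcount, charge = _parse_bracket_atom(token)
                out.append(
                    _atom_selfies_token(pending_bond, elem, hcount, charge)
                )
            else:
                if token.islower():
                    raise SelfiesEncodeError(
                        f"aromatic atom {token!r} after kekulization"
                    )
                out.append(_atom_selfies_token(pending_bond, token, None, 0))
            self.n_atoms += 1
            pending_bond = 1


def encode(smiles: str) -> str:
    """Encode a SMILES string; stereochemistry and isotopes are dropped."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SelfiesEncodeError(f"cannot parse SMILES {smiles!r}")
    if len(Chem.GetMolFrags(mol)) > 1:
        raise SelfiesEncodeError("disconnected fragments are not encodable")
    Chem.RemoveStereochemistry(mol)
    for atom in mol.GetAtoms():
        atom.SetIsotope(0)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    kek = Chem.MolToSmiles(mol, kekuleSmiles=True, canonical=True)

    walk = _SMILES_WALK_RE.findall(kek)
    if "".join(walk) != kek:
        raise SelfiesEncodeError(f"SMILES outside encodable subset: {kek!r}")
    encoder = _Encoder(walk)
    tokens = encoder.encode_chain(at_top=True)
    if encoder.open_rings:
        raise SelfiesEncodeError("unclosed ring bond in SMILES")
    return "".join(tokens)
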