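"""A valence-constrained robust molecular string codec (SELFIES-style).

Molecules are written as a concatenation of bracketed tokens, e.g.
``[C][C][O]`` for ethanol or ``[C][=C][C][=C][C][=C][Ring5]`` for benzene.
The decoder is a small state machine that can never produce an atom with more
bonds than its standard valence: bond orders are capped at the remaining
capacity of the attachment atom, ring tokens that cannot be realized are
skipped, and decoding simply stops when no capacity is left. Consequently
**every string of tokens drawn from the codec alphabet decodes to a valid
molecule** — the property that makes language models trained on this
representation produce 100% valid samples at any training stage.

This is a self-contained implementation of the robust-representation idea
(bracket tokens + valence-capped derivation). It is *not* byte-compatible
with the reference SELFIES library: branches are delimited with explicit
``[Branch]``/``[EndBranch]`` tokens and ring closures name their placement
offset directly (``[Ring3]`` bonds the current atom to the atom placed three
positions earlier).

Supported chemistry: neutral organic molecules over C, N, O, S, P and the
halogens at standard valence, with aromaticity carried through the Kekulé
structure. Charges, isotopes, radicals and stereochemistry are outside the
codec's domain; :func:`encode` raises :class:`CodecUnsupported` for them.
"""

from __future__ import annotations

import re

from rdkit import Chem

# Standard (maximum encodable) valence per element. Hypervalent states
# (e.g. sulfone S) are deliberately not representable: the decode guarantee
# rests on never exceeding these caps.
VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3,
           "F": 1, "Cl": 1, "Br": 1, "I": 1}

BOND_PREFIX = {1: "", 2: "=", 3: "#"}
PREFIX_BOND = {"": 1, "=": 2, "#": 3}

_TOKEN_RE = re.compile(r"\[[^\[\]]*\]")
_ATOM_RE = re.compile(r"^\[(=|#)?(C|N|O|S|P|F|Cl|Br|I)\]$")
_RING_RE = re.compile(r"^\[(=)?Ring([1-9][0-9]?)\]$")

BRANCH, END_BRANCH = "[Branch]", "[EndBranch]"


class CodecError(ValueError):
    """Malformed robust string (stray characters, unknown token)."""


class CodecUnsupported(ValueError):
    """Molecule uses chemistry outside the codec's domain."""


def split_tokens(s: str) -> list[str]:
    """Split a robust string into bracket tokens; reject stray characters."""
    tokens = []
    pos = 0
    for m in _TOKEN_RE.finditer(s):
        if m.start() != pos:
            raise CodecError(f"stray characters at position {pos}: {s[pos:m.start()]!r}")
        tokens.append(m.group(0))
        pos = m.end()
    if pos != len(s):
        raise CodecError(f"stray characters at position {pos}: {s[pos:]!r}")
    return tokens


def alphabet(max_ring: int = 20) -> list[str]:
    """The full token alphabet with ring offsets up to ``max_ring``."""
    tokens = [BRANCH, END_BRANCH]
    for el in VALENCE:
        for p, order in PREFIX_BOND.items():
            if order <= VALENCE[el]:
                tokens.append(f"[{p}{el}]")
    for n in range(1, max_ring + 1):
        tokens.append(f"[Ring{n}]")
        tokens.append(f"[=Ring{n}]")
    return tokens


def decode(s: str | list[str]) -> str:
    """Decode a robust string (or token list) to SMILES.

    Never fails on alphabet-conformant input: impossible bonds are capped or
    skipped rather than raising. Raises :class:`CodecError` only for strings
    that are not sequences of known bracket tokens.
    """
    tokens = split_tokens(s) if isinstance(s, str) else list(s)
    mol = Chem.RWMol()
    free: list[int] = []          # remaining valence per atom, placement order
    cur = -1                      # attachment atom index
    stack: list[int] = []         # branch return points

    for tok in tokens:
        if tok == BRANCH:
            if cur >= 0:
                stack.append(cur)
            continue
        if tok == END_BRANCH:
            if stack:
                cur = stack.pop()
            continue
        m = _ATOM_RE.match(tok)
        if m:
            prefix, el = m.group(1) or "", m.group(2)
            want = PREFIX_BOND[prefix]
            if cur < 0:
                idx = mol.AddAtom(Chem.Atom(el))
                free.append(VALENCE[el])
                cur = idx
                continue
            # walk up the branch stack to the nearest atom with capacity
            while free[cur] == 0 and stack:
                cur = stack.pop()
            if free[cur] == 0:
                break  # derivation exhausted: no atom can accept more bonds
            order = min(want, free[cur], VALENCE[el])
            idx = mol.AddAtom(Chem.Atom(el))
            free.append(VALENCE[el] - order)
            mol.AddBond(cur, idx, Chem.BondType.values[order])
            free[cur] -= order
            cur = idx
            continue
        m = _RING_RE.match(tok)
        if m:
            want = 2 if m.group(1) else 1
            back = int(m.group(2))
            target = cur - back
            if cur < 0 or target < 0:
                continue  # not enough atoms placed yet: skip
            if mol.GetBondBetweenAtoms(cur, target) is not None:
                continue  # duplicate closure: skip
            order = min(want, free[cur], free[target])
            if order == 0:
                continue  # no capacity on one endpoint: skip
            mol.AddBond(cur, target, Chem.BondType.values[order])
            free[cur] -= order
            free[target] -= order
            continue
        raise CodecError(f"unknown token {tok!r}")

    if mol.GetNumAtoms() == 0:
        # structural tokens only (or the empty token list): the derivation
        # root is an implicit carbon, so such strings decode to methane —
        # every alphabet string yields a molecule, without exception
        return "C"
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def _check_encodable(mol: Chem.Mol) -> None:
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in VALENCE:
            raise CodecUnsupported(f"element {sym} not in codec alphabet")
        if atom.GetFormalCharge() != 0:
            raise CodecUnsupported("charged atoms are not encodable")
        if atom.GetIsotope() != 0 or atom.GetNumRadicalElectrons() != 0:
            raise CodecUnsupported("isotopes/radicals are not encodable")
    if Chem.FindMolChiralCenters(mol, includeUnassigned=False):
        pass  # stereo centres are silently flattened; codec carries no stereo


def encode(smiles_or_mol: str | Chem.Mol) -> str:
    """Encode a molecule as a robust bracket-token string.

    The Kekulé structure is written (aromaticity is re-perceived on decode);
    stereochemistry is dropped. Raises :class:`CodecUnsupported` for charged,
    hypervalent or exotic-element molecules.
    """
    if isinstance(smiles_or_mol, str):
        mol = Chem.MolFromSmiles(smiles_or_mol)
        if mol is None:
            raise CodecUnsupported(f"unparseable SMILES {smiles_or_mol!r}")
    else:
        mol = Chem.Mol(smiles_or_mol)
    _check_encodable(mol)
    mol = Chem.Mol(mol)
    Chem.RemoveStereochemistry(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    for atom in mol.GetAtoms():
        order = int(sum(b.GetBondTypeAsDouble() for b in atom.GetBonds()))
        if order > VALENCE[atom.GetSymbol()]:
            raise CodecUnsupported(
                f"{atom.GetSymbol()} with bond order {order} exceeds codec valence"
            )

    place: dict[int, int] = {}    # atom idx -> placement position
    tokens: list[str] = []
    closed: set[frozenset[int]] = set()

    def emit(u: int, bond_order: int, parent: int | None) -> None:
        place[u] = len(place)
        tokens.append(f"[{BOND_PREFIX[bond_order]}{mol.GetAtomWithIdx(u).GetSymbol()}]")
        nbrs = []
        for b in mol.GetAtomWithIdx(u).GetBonds():
            v = b.GetOtherAtomIdx(u)
            if v == parent:
                continue
            order = int(b.GetBondTypeAsDouble())
            if v in place:  # ring closure back-edge
                key = frozenset((u, v))
                if key not in closed:
                    closed.add(key)
                    p = "=" if order == 2 else ""
                    tokens.append(f"[{p}Ring{place[u] - place[v]}]")
            else:
                nbrs.append((v, order))
        for i, (v, order) in enumerate(nbrs):
            if v in place:
                # placed by a deeper recursion since nbrs was computed: the
                # bond was emitted there as a ring closure (v saw u placed)
                assert frozenset((u, v)) in closed
                continue
            last = i == len(nbrs) - 1
            if not last:
                tokens.append(BRANCH)
            emit(v, order, u)
            if not last:
                tokens.append(END_BRANCH)

    if mol.GetNumAtoms() == 0:
        raise CodecUnsupported("empty molecule")
    emit(0, 1, None)
    return "".join(tokens)
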