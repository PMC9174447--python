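"""Structural analyses for large-molecule batches.

Fragment decomposition cuts every acyclic single bond (single-order bonds not
in any ring) and takes the resulting connected components as fragments —
the simplest convention that yields the single-atom / single-ring /
fused-ring categories used in the per-molecule profiles. Amino-acid content
is counted on the *intact* molecule by substructure search against a fixed
library of 20 residue patterns, each encoding the backbone N-Calpha-C(=O)
motif plus the residue's side chain; overlapping matches of one pattern are
counted once per distinct alpha carbon. Nearest-neighbour search uses Morgan
circular fingerprints (radius 2, 2048 bits) and Tanimoto similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .molio import MoleculeRecord, MoleculeSet

# Residue substructure patterns. Backbone nitrogen is any non-aromatic
# trivalent N (so chain-internal amide N and terminal amine both match);
# proline uses its ring-closed backbone. Side chains carry explicit
# H-count/degree constraints where needed to keep residues mutually
# exclusive (Ala vs Val vs Leu vs Ile vs Thr etc.).
AA_SMARTS: dict[str, str] = {
    "A": "[NX3;!$(N=*)][CX4H1]([CH3])[CX3](=O)",
    "C": "[NX3;!$(N=*)][CX4H1]([CH2][SX2H1])[CX3](=O)",
    "D": "[NX3;!$(N=*)][CX4H1]([CH2][CX3](=O)[OX2H1,OX1-])[CX3](=O)",
    "E": "[NX3;!$(N=*)][CX4H1]([CH2][CH2][CX3](=O)[OX2H1,OX1-])[CX3](=O)",
    "F": "[NX3;!$(N=*)][CX4H1]([CH2]c1[cH][cH][cH][cH][cH]1)[CX3](=O)",
    "G": "[NX3;!$(N=*)][CX4H2][CX3](=O)",
    "H": "[NX3;!$(N=*)][CX4H1]([CH2]c1c[nH]cn1)[CX3](=O)",
    "I": "[NX3;!$(N=*)][CX4H1]([CX4H1]([CH3])[CH2][CH3])[CX3](=O)",
    "K": "[NX3;!$(N=*)][CX4H1]([CH2][CH2][CH2][CH2][NX3H2])[CX3](=O)",
    "L": "[NX3;!$(N=*)][CX4H1]([CH2][CX4H1]([CH3])[CH3])[CX3](=O)",
    "M": "[NX3;!$(N=*)][CX4H1]([CH2][CH2][SX2][CH3])[CX3](=O)",
    "N": "[NX3;!$(N=*)][CX4H1]([CH2][CX3](=O)[NX3H2])[CX3](=O)",
    "P": "[NX3;!$(N=*)]1[CH2][CH2][CH2][CX4H1]1[CX3](=O)",
    "Q": "[NX3;!$(N=*)][CX4H1]([CH2][CH2][CX3](=O)[NX3H2])[CX3](=O)",
    "R": "[NX3;!$(N=*)][CX4H1]([CH2][CH2][CH2][NX3][CX3](=[NX2])[NX3H2])[CX3](=O)",
    "S": "[NX3;!$(N=*)][CX4H1]([CH2][OX2H1])[CX3](=O)",
    "T": "[NX3;!$(N=*)][CX4H1]([CX4H1]([CH3])[OX2H1])[CX3](=O)",
    "V": "[NX3;!$(N=*)][CX4H1]([CX4H1]([CH3])[CH3])[CX3](=O)",
    "W": "[NX3;!$(N=*)][CX4H1]([CH2]c1c[nH]c2ccccc12)[CX3](=O)",
    "Y": "[NX3;!$(N=*)][CX4H1]([CH2]c1[cH][cH]c([OX2H1])[cH][cH]1)[CX3](=O)",
}
# index of the alpha carbon within each pattern's match tuple
_CA_POSITION = {aa: (1 if aa != "P" else 4) for aa in AA_SMARTS}

_AA_PATTERNS = {aa: Chem.MolFromSmarts(s) for aa, s in AA_SMARTS.items()}
assert all(p is not None for p in _AA_PATTERNS.values())


@dataclass(frozen=True)
class FragmentProfile:
    """Per-molecule fragment and residue counts."""

    n_fragments: int
    n_single_atom: int
    n_single_ring: int
    n_fused_ring: int
    n_amino_acid: int
    per_residue: dict[str, int]

    def __post_init__(self) -> None:
        assert (self.n_single_atom + self.n_single_ring + self.n_fused_ring
                <= self.n_fragments)


def _require_mol(record: MoleculeRecord) -> Chem.Mol:
    if not record.is_valid:
        raise ValueError(f"invalid record {record.raw_string!r}")
    return record.mol()


def count_amino_acids(record: MoleculeRecord) -> dict[str, int]:
    """Residue -> count of substructure matches, one per distinct alpha carbon."""
    mol = _require_mol(record)
    counts: dict[str, int] = {}
    for aa, patt in _AA_PATTERNS.items():
        matches = mol.GetSubstructMatches(patt)
        alphas = {m[_CA_POSITION[aa]] for m in matches}
        counts[aa] = len(alphas)
    return counts


def fragment_decompose(record: MoleculeRecord) -> FragmentProfile:
    """Cut all acyclic single bonds; profile the resulting fragments.

    Classification: single-atom = one heavy atom; single-ring = exactly one
    ring; fused-ring = two or more rings sharing at least one atom. The
    amino-acid count comes from :func:`count_amino_acids` on the intact
    molecule, not from the cut fragments.
    """
    mol = _require_mol(record)
    # connected components of the graph with acyclic single bonds deleted;
    # working on the intact parent avoids re-sanitizing cut aromatic systems
    n = mol.GetNumAtoms()
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for b in mol.GetBonds():
        if b.GetBondType() == Chem.BondType.SINGLE and not b.IsInRing():
            continue  # this bond is cut
        ra, rb = find(b.GetBeginAtomIdx()), find(b.GetEndAtomIdx())
        if ra != rb:
            parent[ra] = rb
    components: dict[int, set[int]] = {}
    for a in range(n):
        components.setdefault(find(a), set()).add(a)

    rings = [set(r) for r in Chem.GetSymmSSSR(mol)]
    n_single_atom = n_single_ring = n_fused = 0
    for atoms in components.values():
        comp_rings = [r for r in rings if r <= atoms]
        if len(atoms) == 1:
            n_single_atom += 1
        elif len(comp_rings) == 1:
            n_single_ring += 1
        elif len(comp_rings) >= 2:
            shares = any(
                comp_rings[i] & comp_rings[j]
                for i in range(len(comp_rings))
                for j in range(i + 1, len(comp_rings))
            )
            if shares:
                n_fused += 1
    frags = components
    residues = count_amino_acids(record)
    return FragmentProfile(
        n_fragments=len(frags),
        n_single_atom=n_single_atom,
        n_single_ring=n_single_ring,
        n_fused_ring=n_fused,
        n_amino_acid=sum(residues.values()),
        per_residue=residues,
    )


_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def fingerprint(record: MoleculeRecord):
    return _FP_GEN.GetFingerprint(_require_mol(record))


def tanimoto(a: MoleculeRecord, b: MoleculeRecord) -> float:
    """Tanimoto similarity of Morgan fingerprints: |on-bit intersection| / |union|."""
    return float(DataStructs.TanimotoSimilarity(fingerprint(a), fingerprint(b)))


def tanimoto_nearest(
    gen: MoleculeSet, reference: MoleculeRecord, top_k: int = 5
) -> list[tuple[MoleculeRecord, float]]:
    """Top-k molecules of ``gen`` by Tanimoto similarity to ``reference``.

    Sorted descending; ties broken by canonical-SMILES order for determinism.
    """
    if not gen.valid:
        raise ValueError("no valid molecules to search")
    ref_fp = fingerprint(reference)
    scored = [
        (r, float(DataStructs.TanimotoSimilarity(fingerprint(r), ref_fp)))
        for r in gen.valid
    ]
    scored.sort(key=lambda t: (-t[1], t[0].canonical_smiles))
    return scored[:top_k]
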