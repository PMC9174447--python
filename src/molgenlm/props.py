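"""Per-molecule property battery used throughout the evaluation.

Descriptors are the chemistry toolkit's standard implementations: LogP by
Wildman-Crippen atomic contributions, SA by the Ertl-Schuffenhauer fragment
score (1 easy .. 10 hard), QED by Bickerton desirability, Bertz complexity,
NP-likeness by the Ertl natural-product fragment score, and exact molecular
weight. Penalized LogP is the raw (non-normalized) composite

    plogp = LogP - SA - #(rings with more than 6 atoms)

on the scale used by the benchmark works this task follows (screen threshold
4.0, tail at 6.0). Ring counting for the penalty uses the smallest set of
smallest rings. The longest carbon chain is the longest simple path in the
carbon-carbon bond subgraph, found by exhaustive search.
"""

from __future__ import annotations

import importlib.util
import math
import os
import sys
from dataclasses import dataclass
from functools import lru_cache

from rdkit import Chem, RDConfig, RDLogger

# the NP fragment scorer emits a per-call fingerprint deprecation notice
RDLogger.DisableLog("rdApp.warning")
from rdkit.Chem import Crippen, Descriptors, GraphDescriptors, QED, rdMolDescriptors

from .molio import MoleculeRecord

PROPERTY_NAMES = ("logp", "sa", "qed", "mw", "bertz", "np")


def _load_contrib(subdir: str, module: str):
    path = os.path.join(RDConfig.RDContribDir, subdir, module + ".py")
    spec = importlib.util.spec_from_file_location(module, path)
    mod = importlib.util.module_from_spec(spec)
    sys.modules.setdefault(module, mod)
    spec.loader.exec_module(mod)
    return mod


@lru_cache(maxsize=1)
def _sascorer():
    return _load_contrib("SA_Score", "sascorer")


@lru_cache(maxsize=1)
def _npscorer():
    mod = _load_contrib("NP_Score", "npscorer")
    import contextlib, io

    with contextlib.redirect_stdout(io.StringIO()), \
            contextlib.redirect_stderr(io.StringIO()):
        model = mod.readNPModel()
    return mod, model


@dataclass(frozen=True)
class PropertyRow:
    """All per-molecule property values used in the distribution comparisons."""

    logp: float
    sa: float
    qed: float
    mw: float
    bertz: float
    np: float
    plogp: float
    n_atoms: int
    n_rings: int
    longest_chain: int

    def get(self, name: str) -> float:
        return getattr(self, name)


def _require_mol(record: MoleculeRecord) -> Chem.Mol:
    if not record.is_valid:
        raise ValueError(
            f"cannot compute properties of invalid record {record.raw_string!r}"
        )
    return record.mol()


def _ring_penalty(mol: Chem.Mol) -> int:
    """Number of SSSR rings with more than 6 atoms ("unrealistic" rings)."""
    return sum(1 for ring in Chem.GetSymmSSSR(mol) if len(ring) > 6)


def penalized_logp(record: MoleculeRecord) -> float:
    """Raw penalized LogP: LogP - SA - #(rings larger than 6 atoms)."""
    mol = _require_mol(record)
    return (
        Crippen.MolLogP(mol)
        - _sascorer().calculateScore(mol)
        - _ring_penalty(mol)
    )


def longest_carbon_chain(record: MoleculeRecord) -> int:
    """Length (atom count) of the longest simple path of C-C bonded carbons.

    Exhaustive depth-first search over the carbon subgraph; tractable at the
    molecule sizes this package handles. A molecule without carbon scores 0.
    """
    mol = _require_mol(record)
    carbons = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "C"]
    if not carbons:
        return 0
    neighbors: dict[int, list[int]] = {c: [] for c in carbons}
    cset = set(carbons)
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if a in cset and b in cset:
            neighbors[a].append(b)
            neighbors[b].append(a)

    best = 1

    def dfs(node: int, visited: set[int], length: int) -> None:
        nonlocal best
        best = max(best, length)
        for nb in neighbors[node]:
            if nb not in visited:
                visited.add(nb)
                dfs(nb, visited, length + 1)
                visited.remove(nb)

    for start in carbons:
        dfs(start, {start}, 1)
    return best


def compute_properties(record: MoleculeRecord) -> PropertyRow:
    """Populate the full property row for a valid record.

    Deterministic for a given canonical form (all descriptors run on the
    canonical molecule, so SMILES respellings give identical rows).
    """
    mol = _require_mol(record)
    npscorer, np_model = _npscorer()
    try:
        logp = Crippen.MolLogP(mol)
        sa = _sascorer().calculateScore(mol)
        qed = QED.qed(mol)
        mw = Descriptors.ExactMolWt(mol)
        bertz = GraphDescriptors.BertzCT(mol)
        np_score = npscorer.scoreMol(mol, np_model)
    except Exception as exc:  # pragma: no cover - descriptor failures are rare
        raise RuntimeError(
            f"descriptor failure on {record.canonical_smiles!r}: {exc}"
        ) from exc
    row = PropertyRow(
        logp=logp, sa=sa, qed=qed, mw=mw, bertz=bertz, np=np_score,
        plogp=logp - sa - _ring_penalty(mol),
        n_atoms=mol.GetNumHeavyAtoms(),
        n_rings=rdMolDescriptors.CalcNumRings(mol),
        longest_chain=longest_carbon_chain(record),
    )
    if not (0.0 <= row.qed <= 1.0) or not (1.0 <= row.sa <= 10.0):
        raise RuntimeError(f"descriptor out of range on {record.canonical_smiles!r}")
    if math.isnan(row.bertz) or math.isnan(row.np):
        raise RuntimeError(f"descriptor NaN on {record.canonical_smiles!r}")
    return row


def heavy_atom_count(record: MoleculeRecord) -> int:
    return _require_mol(record).GetNumHeavyAtoms()
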