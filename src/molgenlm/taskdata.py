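"""Task training-set builders and the synthetic molecule-pool generator.

Three "complex distribution" training sets are supported:

* **logp** — molecules screened for penalized LogP strictly above 4.0;
* **multi** — a four-mode mixture over molecular-weight windows
  (MW <= 185; 185 <= MW <= 425; 460 <= MW <= 600; MW > 600) with component
  fractions 1/6 : 1/3 : 1/6 : 1/3 — the small-molecule and photovoltaic
  windows jointly contribute one third, the drug-like and polymer windows one
  third each;
* **large** — molecules with strictly more than 100 heavy atoms.

The synthetic pool generator stands in for the public databases those sets
are drawn from at full scale (drug-like screening libraries, exhaustive
small-molecule enumerations, photovoltaic and polymer collections, and the
largest biomolecule-rich entries of compound registries), so the entire
pipeline runs without downloads. Pools are deterministic for a given seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from . import props
from .molio import MoleculeRecord, MoleculeSet, molecule_set, parse_molecule

logger = logging.getLogger(__name__)

# Molecular-weight windows of the multi-distribution task, in g/mol.
# Boundaries are inclusive as printed except the strict "MW > 600".
MULTI_WINDOWS: dict[str, tuple[float, float]] = {
    "gdb13": (0.0, 185.0),
    "zinc": (185.0, 425.0),
    "cep": (460.0, 600.0),
    "polymers": (600.0, float("inf")),
}
# Component fractions; the joint-one-third reading gives the enumeration
# pools 1/6 each. Overridable via compose_multimodal(fractions=...).
MULTI_FRACTIONS: dict[str, float] = {
    "gdb13": 1 / 6, "zinc": 1 / 3, "cep": 1 / 6, "polymers": 1 / 3,
}


@dataclass(frozen=True)
class TaskSpec:
    """A task name plus its screening / composition parameters."""

    task: str  # logp | multi | large
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task not in ("logp", "multi", "large"):
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def primary_property(self) -> str:
        return "plogp" if self.task == "logp" else "mw"


def _in_window(mw: float, window: tuple[float, float], name: str) -> bool:
    lo, hi = window
    if name == "polymers":
        return mw > lo
    return lo <= mw <= hi


def screen_penalized_logp(pool: MoleculeSet, threshold: float = 4.0) -> MoleculeSet:
    """Valid molecules with penalized LogP strictly above ``threshold``."""
    out = [r for r in pool.valid if props.penalized_logp(r) > threshold]
    if not out:
        logger.warning("penalized-LogP screen at %.2f left no molecules", threshold)
    return MoleculeSet(records=out, name=f"{pool.name}-plogp>{threshold:g}")


def screen_large(pool: MoleculeSet, min_heavy_exclusive: int = 100) -> MoleculeSet:
    """Valid molecules with strictly more than ``min_heavy_exclusive`` heavy atoms."""
    out = [r for r in pool.valid
           if props.heavy_atom_count(r) > min_heavy_exclusive]
    return MoleculeSet(records=out, name=f"{pool.name}-large>{min_heavy_exclusive}")


def compose_multimodal(
    pools: dict[str, MoleculeSet],
    total: int,
    seed: int = 0,
    fractions: dict[str, float] | None = None,
) -> MoleculeSet:
    """Mix the four MW-window pools into one training set of size ``total``.

    Every pool is validated against its window (violators raise, listed);
    quotas are the rounded fractions (largest-remainder rounding, so counts
    deviate from exact fractions by at most 1 and sum to ``total``); each
    pool is subsampled uniformly without replacement with the given seed.
    """
    fractions = dict(fractions or MULTI_FRACTIONS)
    unknown = set(pools) - set(MULTI_WINDOWS)
    if unknown:
        raise ValueError(f"unknown window pools: {sorted(unknown)}")
    missing = set(fractions) - set(pools)
    if missing:
        raise ValueError(f"pools missing for windows: {sorted(missing)}")
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("window fractions must sum to 1")

    for name, mol_set in pools.items():
        window = MULTI_WINDOWS[name]
        violators = [
            r.canonical_smiles for r in mol_set.valid
            if not _in_window(
                Descriptors.ExactMolWt(Chem.MolFromSmiles(r.canonical_smiles)),
                window, name)
        ]
        if violators:
            raise ValueError(
                f"pool {name!r} has {len(violators)} molecules outside its MW "
                f"window {window}: {violators[:5]}"
            )

    # largest-remainder quota rounding
    names = sorted(fractions)
    exact = {n: fractions[n] * total for n in names}
    quota = {n: int(exact[n]) for n in names}
    leftover = total - sum(quota.values())
    for n in sorted(names, key=lambda n: exact[n] - quota[n], reverse=True)[:leftover]:
        quota[n] += 1

    rng = np.random.default_rng(seed)
    records = []
    for name in names:
        valid = pools[name].valid
        if len(valid) < quota[name]:
            raise ValueError(
                f"pool {name!r} too small: need {quota[name]}, have {len(valid)}"
            )
        idx = rng.choice(len(valid), size=quota[name], replace=False)
        records.extend(valid[i] for i in sorted(idx))
    return MoleculeSet(records=records, name=f"multi-{total}")


# ---------------------------------------------------------------------------
# synthetic pools

_DRUGLIKE_CORES = [
    "c1ccccc1", "c1ccncc1", "c1ccc2ccccc2c1", "c1cc[nH]c1", "c1ccsc1",
    "c1ccoc1", "C1CCCCC1", "C1CCNCC1", "C1CCOCC1", "c1cnc[nH]1",
]
_DRUGLIKE_SUBS = [
    "C", "CC", "CCC", "O", "OC", "N", "NC", "F", "Cl", "Br", "C(=O)O",
    "C(=O)N", "C(=O)C", "C#N", "S", "SC", "CO", "CN", "C(C)C", "CCO", "CCN",
]
_LINKERS = ["", "C", "CC", "CCC", "O", "N", "C(=O)", "C(=O)N", "S"]

# Chain-growth units for MW-window pools: molecules are mixed-monomer chains
# grown toward a uniformly drawn target mass inside the window, emulating the
# oligomeric character of the polymer/photovoltaic collections and giving each
# window a quasi-continuous molecular-weight distribution.
_MONOMERS = ["CC", "CCO", "CC(C)", "CC(=O)N", "Cc1ccccc1", "CO", "CN",
             "Cc1ccsc1", "CC(=O)O", "CCS", "CCCO", "CC(C)O"]
_END_CAPS = ["", "C", "CC", "CCC", "O", "CO", "N", "CN"]

_AA_SIDE_CHAINS: dict[str, str | None] = {
    "A": "C", "C": "CS", "D": "CC(O)=O", "E": "CCC(O)=O", "F": "Cc1ccccc1",
    "G": None, "H": "Cc1c[nH]cn1", "I": "C(C)CC", "K": "CCCCN",
    "L": "CC(C)C", "M": "CCSC", "N": "CC(N)=O", "P": "proline",
    "Q": "CCC(N)=O", "R": "CCCNC(=N)N", "S": "CO", "T": "C(C)O",
    "V": "C(C)C", "W": "Cc1c[nH]c2ccccc12", "Y": "Cc1ccc(O)cc1",
}
AMINO_ACIDS = tuple(sorted(_AA_SIDE_CHAINS))


def peptide_smiles(sequence: str) -> str:
    """Linear peptide SMILES (no stereocenters) for a one-letter sequence."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    units = []
    for aa in sequence:
        if aa not in _AA_SIDE_CHAINS:
            raise ValueError(f"unknown residue {aa!r}")
        side = _AA_SIDE_CHAINS[aa]
        if aa == "P":
            units.append("N3CCCC3C(=O)")  # ring-closed backbone
        elif side is None:
            units.append("NCC(=O)")  # glycine
        else:
            units.append(f"NC({side})C(=O)")
    return "".join(units) + "O"


def _assemble_druglike(rng: np.random.Generator) -> str:
    """Grow a molecule by prepending substituent+linker groups onto random
    attachment atoms of a ring core; chemically impossible attachments are
    simply rejected by the parser and skipped."""
    core = _DRUGLIKE_CORES[rng.integers(len(_DRUGLIKE_CORES))]
    mol = Chem.MolFromSmiles(core)
    for _ in range(rng.integers(1, 5)):
        sub = _DRUGLIKE_SUBS[rng.integers(len(_DRUGLIKE_SUBS))]
        link = _LINKERS[rng.integers(len(_LINKERS))]
        root = int(rng.integers(mol.GetNumAtoms()))
        rooted = Chem.MolToSmiles(mol, rootedAtAtom=root, canonical=False)
        new = Chem.MolFromSmiles(f"{sub}{link}{rooted}")
        if new is not None:
            mol = new
    return Chem.MolToSmiles(mol)


def make_synthetic_pool(kind: str, n: int, seed: int = 0, **kwargs) -> MoleculeSet:
    """Deterministic synthetic molecule pools emulating the source databases.

    Kinds:

    * ``druglike`` — ring/chain molecules from a fragment grammar, kept to
      MW 150-450 (screening-library regime);
    * ``window`` — molecules rejection-sampled into a target MW window
      ``(lo, hi)`` from an oligomer grammar (supports the four multi-task
      modes; pass ``lo=...``, ``hi=...``);
    * ``highlogp`` — long-carbon-chain, ring-poor molecules, the motif of the
      high penalized-LogP tail (majority scoring above 4.0);
    * ``peptide`` — linear peptides of uniformly random standard residues
      (``length=`` residues, default 19; large-task biomolecule mode);
    * ``alkane`` — the linear alkane series C(k1)..C(k2) (``k1=``, ``k2=``),
      one molecule per length, cycled to reach ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    strings: list[str] = []
    if kind == "druglike":
        lo, hi = kwargs.get("lo", 150.0), kwargs.get("hi", 450.0)
        strings = _rejection_pool(
            lambda: _assemble_druglike(rng), n, lo, hi,
            max_tries=kwargs.get("max_tries", 200 * n))
    elif kind == "window":
        lo, hi = float(kwargs["lo"]), float(kwargs["hi"])
        strings = _rejection_pool(
            lambda: _assemble_oligomer(rng, lo, hi), n, lo, hi,
            max_tries=kwargs.get("max_tries", 400 * n))
    elif kind == "highlogp":
        for _ in range(n):
            length = int(rng.integers(16, 36))
            chain = ["C"] * length
            # sparse methyl decoration keeps chains dominant, rings absent
            for pos in range(2, length - 2):
                if rng.random() < 0.08:
                    chain[pos] = "C(C)"
            strings.append("".join(chain))
    elif kind == "peptide":
        length = int(kwargs.get("length", 19))
        for _ in range(n):
            seq = "".join(AMINO_ACIDS[i]
                          for i in rng.integers(len(AMINO_ACIDS), size=length))
            strings.append(peptide_smiles(seq))
    elif kind == "alkane":
        k1, k2 = int(kwargs.get("k1", 1)), int(kwargs.get("k2", 20))
        if k1 < 1 or k2 < k1:
            raise ValueError("alkane pool needs 1 <= k1 <= k2")
        lengths = list(range(k1, k2 + 1))
        strings = ["C" * lengths[i % len(lengths)] for i in range(n)]
    else:
        raise ValueError(f"unknown pool kind {kind!r}")
    out = molecule_set(strings, "smiles", name=f"{kind}-{n}", source_tag=kind)
    bad = [r for r in out.records if not r.is_valid]
    assert not bad, f"generator produced invalid strings: {bad[:3]}"
    return out


@lru_cache(maxsize=None)
def _unit_mass(monomer: str) -> tuple[float, float]:
    """Linear fit mass(k) ~= slope*k + intercept for the k-fold repeat."""
    m1 = Descriptors.ExactMolWt(Chem.MolFromSmiles(monomer))
    m2 = Descriptors.ExactMolWt(Chem.MolFromSmiles(monomer * 2))
    return m2 - m1, 2 * m1 - m2


def _assemble_oligomer(rng: np.random.Generator, lo: float, hi: float) -> str:
    # centre-weighted target mass gives each window a unimodal hump rather
    # than a flat plateau, as in the real screened collections
    centre, spread = 0.5 * (lo + hi), (hi - lo) / 6.0
    target = float(np.clip(rng.normal(centre, spread), lo, hi))
    parts: list[str] = []
    mass = 18.0  # chain-end hydrogens, roughly
    while mass < target - 45.0:
        monomer = _MONOMERS[rng.integers(len(_MONOMERS))]
        parts.append(monomer)
        mass += _unit_mass(monomer)[0]
    parts.append(_END_CAPS[rng.integers(len(_END_CAPS))])
    return "".join(parts) or "C"


def _rejection_pool(sampler, n, lo, hi, max_tries) -> list[str]:
    """Sample until n molecules fall in the MW window; every pool molecule
    must also be representable in the robust bracket encoding so the same
    pool can train both model families."""
    from .selfies_codec import CodecUnsupported, encode as rs_encode

    out: list[str] = []
    tries = 0
    while len(out) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"MW window [{lo}, {hi}] infeasible: {len(out)}/{n} molecules "
                f"after {max_tries} draws"
            )
        tries += 1
        s = sampler()
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            continue
        if not lo <= Descriptors.ExactMolWt(mol) <= hi:
            continue
        try:
            rs_encode(mol)
        except CodecUnsupported:
            continue
        out.append(s)
    return out


def dataset_stats(mol_set: MoleculeSet) -> dict[str, float]:
    """Min/mean/max heavy-atom and ring counts (summary-table format)."""
    rows = [props.compute_properties(r) for r in mol_set.valid]
    if not rows:
        raise ValueError("no valid molecules")
    atoms = [r.n_atoms for r in rows]
    rings = [r.n_rings for r in rows]
    return {
        "n": len(rows),
        "atoms_min": min(atoms), "atoms_mean": sum(atoms) / len(atoms),
        "atoms_max": max(atoms),
        "rings_min": min(rings), "rings_mean": sum(rings) / len(rings),
        "rings_max": max(rings),
    }
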