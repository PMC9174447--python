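"""Molecule parsing, canonicalization, deduplication, and line-file I/O.

Every other module consumes :class:`MoleculeRecord` / :class:`MoleculeSet`.
Molecule identity throughout the package is canonical-SMILES string equality:
uniqueness, novelty and overlap removal all compare the canonical form produced
by RDKit. Invalid strings are retained as flagged records (never silently
dropped) so validity statistics can be computed on raw generated output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

# RDKit logs every parse failure to stderr; generated batches contain many.
RDLogger.DisableLog("rdApp.error")

ENCODINGS = ("smiles", "selfies")


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule: the raw string, how it is encoded, and its parsed identity.

    ``is_valid`` is true iff ``canonical_smiles`` is present. For
    ``encoding="selfies"`` the raw string is a bracket-token robust string and
    validity is guaranteed for any alphabet-conformant input (the codec
    contract); for SMILES, validity reflects whether RDKit accepts the string.
    """

    raw_string: str
    encoding: str = "smiles"
    canonical_smiles: str | None = None
    is_valid: bool = False
    source_tag: str = ""
    failure_reason: str | None = None

    def __post_init__(self) -> None:
        if self.encoding not in ENCODINGS:
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if self.is_valid != (self.canonical_smiles is not None):
            raise ValueError("is_valid must mirror presence of canonical_smiles")

    def mol(self) -> Chem.Mol:
        """RDKit molecule for a valid record."""
        if not self.is_valid:
            raise ValueError(
                f"record {self.raw_string!r} is invalid: {self.failure_reason}"
            )
        return Chem.MolFromSmiles(self.canonical_smiles)


@dataclass
class MoleculeSet:
    """An ordered collection of molecule records with a display name."""

    records: list[MoleculeRecord] = field(default_factory=list)
    name: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def valid(self) -> list[MoleculeRecord]:
        return [r for r in self.records if r.is_valid]

    def canonical_set(self) -> set[str]:
        return {r.canonical_smiles for r in self.records if r.is_valid}

    def raw_strings(self) -> list[str]:
        return [r.raw_string for r in self.records]


def parse_molecule(
    raw: str, encoding: str = "smiles", source_tag: str = ""
) -> MoleculeRecord:
    """Parse one molecule string into a record; never raises on bad chemistry.

    SMILES go through RDKit sanitization; robust bracket strings are first
    decoded to SMILES by the codec (which by construction yields a decodable
    structure for any string over its alphabet). An empty string produces an
    invalid record with a failure reason.
    """
    if encoding not in ENCODINGS:
        raise ValueError(f"unknown encoding {encoding!r}")
    if (raw is None or raw == "") and encoding == "smiles":
        return MoleculeRecord(
            raw_string="", encoding=encoding, source_tag=source_tag,
            failure_reason="empty string",
        )
    if encoding == "selfies":
        # the robust decoder is total: even the zero-token string derives a
        # molecule (the implicit root atom), preserving the every-string-is-
        # valid guarantee for sampled batches
        from .selfies_codec import decode as selfies_decode

        try:
            smiles = selfies_decode(raw)
        except Exception as exc:  # malformed brackets, unknown token
            return MoleculeRecord(
                raw_string=raw, encoding=encoding, source_tag=source_tag,
                failure_reason=f"codec: {exc}",
            )
    else:
        smiles = raw
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        return MoleculeRecord(
            raw_string=raw, encoding=encoding, source_tag=source_tag,
            failure_reason="chemistry parser rejected string",
        )
    return MoleculeRecord(
        raw_string=raw,
        encoding=encoding,
        canonical_smiles=Chem.MolToSmiles(mol),
        is_valid=True,
        source_tag=source_tag,
    )


def canonicalize(record: MoleculeRecord) -> str:
    """Deterministic canonical SMILES of a valid record.

    Equal molecules map to equal strings; the output is a fixed point of
    re-canonicalization.
    """
    if not record.is_valid:
        raise ValueError(
            f"cannot canonicalize invalid record {record.raw_string!r} "
            f"({record.failure_reason})"
        )
    return record.canonical_smiles


def molecule_set(
    strings: Iterable[str], encoding: str = "smiles", name: str = "",
    source_tag: str = "",
) -> MoleculeSet:
    """Parse an iterable of raw strings into a MoleculeSet."""
    return MoleculeSet(
        records=[parse_molecule(s, encoding, source_tag) for s in strings],
        name=name,
    )


def read_line_file(path: str | Path, encoding: str = "smiles") -> MoleculeSet:
    """Read a .smi-style line file: one molecule per line, optional tab-separated id.

    Blank lines are skipped (with a logged count); ``#``-prefixed comment lines
    are ignored. A missing file raises ``FileNotFoundError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"molecule file not found: {path}")
    records: list[MoleculeRecord] = []
    n_blank = 0
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.rstrip("\n\r")
        if not line.strip():
            n_blank += 1
            continue
        if line.lstrip().startswith("#"):
            continue
        raw, _, ident = line.partition("\t")
        records.append(parse_molecule(raw.strip(), encoding, ident.strip()))
    if n_blank:
        logger.info("skipped %d blank lines in %s", n_blank, path)
    return MoleculeSet(records=records, name=path.stem)


def write_line_file(mol_set: MoleculeSet, path: str | Path) -> None:
    """Write raw strings (with source tags as tab-separated ids) one per line."""
    path = Path(path)
    lines = []
    for r in mol_set.records:
        lines.append(f"{r.raw_string}\t{r.source_tag}" if r.source_tag else r.raw_string)
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def deduplicate(mol_set: MoleculeSet) -> MoleculeSet:
    """Keep the first occurrence of each canonical form; invalid records kept as-is."""
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    for r in mol_set.records:
        if r.is_valid:
            if r.canonical_smiles in seen:
                continue
            seen.add(r.canonical_smiles)
        out.append(r)
    return MoleculeSet(records=out, name=mol_set.name)


def remove_overlap(mol_set: MoleculeSet, reference: MoleculeSet) -> MoleculeSet:
    """Records of ``mol_set`` whose canonical form is absent from ``reference``.

    Internal duplicates are removed too (first occurrence kept); this is the
    "removing duplicates and training molecules" step of the evaluation
    protocol. Invalid records are dropped here — overlap is defined on
    canonical forms only.
    """
    ref = reference.canonical_set()
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    for r in mol_set.records:
        if not r.is_valid:
            continue
        c = r.canonical_smiles
        if c in ref or c in seen:
            continue
        seen.add(c)
        out.append(r)
    return MoleculeSet(records=out, name=mol_set.name)


def retag(mol_set: MoleculeSet, tag: str) -> MoleculeSet:
    """Return a copy with every record's source_tag replaced."""
    return MoleculeSet(
        records=[replace(r, source_tag=tag) for r in mol_set.records],
        name=mol_set.name,
    )
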