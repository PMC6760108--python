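"""Reading, washing and deduplicating molecule tables.

Input datasets are delimited text files of SMILES strings plus a free-text
identifier.  Before any core enumeration the structures are "washed": salts
are dropped by keeping the largest connected component, stereochemistry is
removed (by default), and the survivor is canonicalized.  Identical washed
structures are collapsed into a single dataset member carrying all original
identifiers, and each member receives a dataset-scoped WID.

Bemis-Murcko scaffolds (ring systems plus linkers, side chains removed) are
computed here as well; they serve as the classical baseline the core
framework is compared against.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

logger = logging.getLogger(__name__)

__all__ = [
    "RawRecord",
    "WashedCandidate",
    "WashedMolecule",
    "ConfigurationError",
    "MoleculeParseError",
    "read_molecule_table",
    "wash_molecule",
    "deduplicate",
    "wash_dataset",
    "murcko_scaffold",
    "write_washed_table",
    "read_washed_table",
    "heavy_atom_count",
]


class ConfigurationError(ValueError):
    """A named column or option is missing or inconsistent."""


class MoleculeParseError(ValueError):
    """A SMILES string could not be parsed into a valid molecule."""


@dataclass(frozen=True)
class RawRecord:
    """One row of an input molecule table, as read."""

    source_id: str
    smiles: str


@dataclass(frozen=True)
class WashedCandidate:
    """A washed structure before dataset-level deduplication (no WID yet)."""

    canonical_smiles: str
    heavy_atoms: int
    source_id: str


@dataclass(frozen=True)
class WashedMolecule:
    """A unique washed dataset member.

    ``wid`` is assigned over the whole dataset by sorted canonical SMILES so
    that identifiers do not depend on input order or parallel chunking.
    """

    wid: str
    canonical_smiles: str
    heavy_atoms: int
    source_ids: tuple[str, ...] = field(default=())


def heavy_atom_count(mol: Chem.Mol) -> int:
    """Number of non-hydrogen, non-wildcard atoms."""
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (0, 1))


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        head = fh.readline()
    if "\t" in head:
        return "\t"
    if "," in head:
        return ","
    return "\t"


def read_molecule_table(
    path: str | Path,
    smiles_column: str = "smiles",
    id_column: str = "id",
    strict: bool = False,
) -> list[RawRecord]:
    """Read a molecule table into :class:`RawRecord` rows, input order kept.

    Two dialects are supported:

    * ``.smi``: whitespace-delimited, SMILES first, identifier second,
      no header (a header line repeating the column names is tolerated
      and skipped).
    * delimited text (TSV/CSV) with a header naming ``smiles_column``
      and ``id_column``.

    Rows with an empty SMILES field are skipped with a warning
    (``strict=True`` aborts instead).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[RawRecord] = []
    if path.suffix.lower() == ".smi":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts:
                    continue
                if lineno == 1 and parts[0].lower() == smiles_column.lower():
                    continue  # tolerated header
                smiles = parts[0]
                source_id = parts[1] if len(parts) > 1 else f"line{lineno}"
                records.append(RawRecord(source_id=source_id, smiles=smiles))
        return records

    delim = _sniff_delimiter(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        for col in (smiles_column, id_column):
            if col not in header:
                raise ConfigurationError(
                    f"column {col!r} not found in {path} (columns: {header})"
                )
        for lineno, row in enumerate(reader, start=2):
            smiles = (row.get(smiles_column) or "").strip()
            source_id = (row.get(id_column) or "").strip()
            if not smiles:
                msg = f"{path}:{lineno}: empty SMILES field, row skipped"
                if strict:
                    raise MoleculeParseError(msg)
                logger.warning(msg)
                continue
            records.append(RawRecord(source_id=source_id, smiles=smiles))
    return records


def _largest_component(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    # most heavy atoms wins; ties broken by lexicographically smallest
    # canonical SMILES so the choice is deterministic across runs
    return min(
        frags,
        key=lambda f: (-heavy_atom_count(f), Chem.MolToSmiles(f)),
    )


def wash_molecule(
    record: RawRecord | str, keep_stereo: bool = False
) -> WashedCandidate:
    """Standardize one structure: largest component, stereo strip, canonicalize.

    Charges are left untouched; washing performs only component selection,
    optional stereo removal and canonicalization, and is idempotent.
    """
    if isinstance(record, str):
        record = RawRecord(source_id="", smiles=record)
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise MoleculeParseError(
            f"unparseable SMILES for {record.source_id!r}: {record.smiles!r}"
        )
    mol = _largest_component(mol)
    if not keep_stereo:
        Chem.RemoveStereochemistry(mol)
    smiles = Chem.MolToSmiles(mol)
    return WashedCandidate(
        canonical_smiles=smiles,
        heavy_atoms=heavy_atom_count(mol),
        source_id=record.source_id,
    )


def _wid_format(n: int) -> str:
    width = max(4, len(str(n)))
    return "W{:0%dd}" % width


def deduplicate(candidates: Sequence[WashedCandidate]) -> list[WashedMolecule]:
    """Collapse identical canonical structures and assign WIDs.

    WIDs follow sorted canonical-SMILES order, so the mapping is independent
    of input order and of how a parallel run chunked the records.
    """
    by_smiles: dict[str, list[str]] = {}
    heavy: dict[str, int] = {}
    for cand in candidates:
        by_smiles.setdefault(cand.canonical_smiles, []).append(cand.source_id)
        heavy[cand.canonical_smiles] = cand.heavy_atoms
    fmt = _wid_format(len(by_smiles))
    out = []
    for i, smi in enumerate(sorted(by_smiles), start=1):
        out.append(
            WashedMolecule(
                wid=fmt.format(i),
                canonical_smiles=smi,
                heavy_atoms=heavy[smi],
                source_ids=tuple(sorted(set(by_smiles[smi]))),
            )
        )
    return out


def wash_dataset(
    records: Iterable[RawRecord],
    keep_stereo: bool = False,
    strict: bool = False,
) -> list[WashedMolecule]:
    """Wash every record and deduplicate; unparseable rows are skipped
    with a warning unless ``strict``."""
    candidates = []
    for rec in records:
        try:
            candidates.append(wash_molecule(rec, keep_stereo=keep_stereo))
        except MoleculeParseError:
            if strict:
                raise
            logger.warning("skipping unparseable record %r", rec.source_id)
    return deduplicate(candidates)


def murcko_scaffold(molecule: WashedMolecule | str | Chem.Mol) -> str | None:
    """Bemis-Murcko framework (rings + linkers, exocyclic multiple bonds
    kept) as canonical SMILES, or ``None`` for an acyclic molecule."""
    if isinstance(molecule, str):
        mol = Chem.MolFromSmiles(molecule)
    elif hasattr(molecule, "canonical_smiles"):
        mol = Chem.MolFromSmiles(molecule.canonical_smiles)
    else:
        mol = molecule
    if mol is None:
        raise MoleculeParseError("invalid molecule for scaffold computation")
    if mol.GetRingInfo().NumRings() == 0:
        return None
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold)


def write_washed_table(molecules: Sequence[WashedMolecule], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["wid", "canonical_smiles", "heavy_atoms", "source_ids"])
        for m in molecules:
            writer.writerow(
                [m.wid, m.canonical_smiles, m.heavy_atoms, ";".join(m.source_ids)]
            )


def read_washed_table(path: str | Path) -> list[WashedMolecule]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                WashedMolecule(
                    wid=row["wid"],
                    canonical_smiles=row["canonical_smiles"],
                    heavy_atoms=int(row["heavy_atoms"]),
                    source_ids=tuple(
                        s for s in row["source_ids"].split(";") if s
                    ),
                )
            )
    return out
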