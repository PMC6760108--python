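"""Inter-dataset overlap of molecules, cores and Bemis-Murcko scaffolds.

Two washed datasets are compared by set algebra on canonical structures at
three levels.  Unique cores per dataset can only exceed or equal unique
molecules (every molecule is its own whole-molecule core), whereas unique
scaffolds can only fall at or below the molecule count (acyclic molecules
contribute none) — the structural contrast the core framework is built on.
A shared core immediately materializes a cross-dataset analog series with
the core itself as its scaffold; a shared Bemis-Murcko scaffold need not.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .chemio import WashedMolecule, murcko_scaffold
from .corenet import MoleculeCoreNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "LevelOverlap",
    "OverlapReport",
    "ConfigMismatchError",
    "dataset_overlap",
    "shared_core_series",
    "write_overlap_report",
]


class ConfigMismatchError(ValueError):
    """The two datasets were enumerated under different configurations."""


@dataclass(frozen=True)
class LevelOverlap:
    """Set algebra at one structural level (canonical-form identity)."""

    count_intra_a: int
    count_intra_b: int
    exclusive_a: int
    exclusive_b: int
    shared: int

    @property
    def union(self) -> int:
        return self.exclusive_a + self.exclusive_b + self.shared

    @property
    def shared_fraction(self) -> float:
        """Shared items as a fraction of the union of both datasets."""
        return self.shared / self.union if self.union else 0.0


@dataclass(frozen=True)
class OverlapReport:
    molecules: LevelOverlap
    cores: LevelOverlap
    scaffolds: LevelOverlap
    core_incidence_a: int  # molecule-core pairs, the non-unique "cores" row
    core_incidence_b: int
    scaffold_incidence_a: int  # molecules bearing a scaffold
    scaffold_incidence_b: int


def _level(sa: set[str], sb: set[str]) -> LevelOverlap:
    return LevelOverlap(
        count_intra_a=len(sa),
        count_intra_b=len(sb),
        exclusive_a=len(sa - sb),
        exclusive_b=len(sb - sa),
        shared=len(sa & sb),
    )


def dataset_overlap(
    net_a: MoleculeCoreNetwork, net_b: MoleculeCoreNetwork
) -> OverlapReport:
    """Compare two enumerated datasets at molecule, core and scaffold level.

    Both networks must have been built with the same enumeration
    configuration, otherwise core identity is not comparable and a
    :class:`ConfigMismatchError` is raised.
    """
    if net_a.config != net_b.config:
        raise ConfigMismatchError(
            "datasets enumerated under different configurations: "
            f"{net_a.config} vs {net_b.config}"
        )
    mols_a = {m.canonical_smiles for m in net_a.molecules.values()}
    mols_b = {m.canonical_smiles for m in net_b.molecules.values()}
    cores_a = {c.canonical_smiles for c in net_a.cores.values()}
    cores_b = {c.canonical_smiles for c in net_b.cores.values()}
    scaf_list_a = [
        s
        for m in net_a.molecules.values()
        if (s := murcko_scaffold(m)) is not None
    ]
    scaf_list_b = [
        s
        for m in net_b.molecules.values()
        if (s := murcko_scaffold(m)) is not None
    ]
    return OverlapReport(
        molecules=_level(mols_a, mols_b),
        cores=_level(cores_a, cores_b),
        scaffolds=_level(set(scaf_list_a), set(scaf_list_b)),
        core_incidence_a=net_a.graph.number_of_edges(),
        core_incidence_b=net_b.graph.number_of_edges(),
        scaffold_incidence_a=len(scaf_list_a),
        scaffold_incidence_b=len(scaf_list_b),
    )


def shared_core_series(
    net_a: MoleculeCoreNetwork,
    net_b: MoleculeCoreNetwork,
    core_smiles: str,
) -> list[tuple[str, str, str]]:
    """Materialize the cross-dataset analog series of one core.

    Returns ``(origin, wid, molecule_smiles)`` rows, origin "A" or "B",
    for every molecule of either dataset incident to the core.  A core
    absent from one side yields a one-sided series with a warning.
    """
    rows: list[tuple[str, str, str]] = []
    for origin, net in (("A", net_a), ("B", net_b)):
        core = net.core_by_smiles(core_smiles)
        if core is None:
            logger.warning("core %r absent from dataset %s", core_smiles, origin)
            continue
        for wid in sorted(net.molecule_wids_of_core(core.mid)):
            rows.append((origin, wid, net.molecules[wid].canonical_smiles))
    return rows


def write_overlap_report(report: OverlapReport, path: str | Path) -> None:
    """Table-shaped TSV: one row per measurement, columns A / B / both."""
    r = report
    rows = [
        ("unique_molecules_intra", r.molecules.count_intra_a,
         r.molecules.count_intra_b, r.molecules.count_intra_a + r.molecules.count_intra_b),
        ("unique_molecules_exclusive", r.molecules.exclusive_a,
         r.molecules.exclusive_b, r.molecules.union),
        ("molecules_shared", "", "", r.molecules.shared),
        ("core_incidence_intra", r.core_incidence_a, r.core_incidence_b,
         r.core_incidence_a + r.core_incidence_b),
        ("unique_cores_intra", r.cores.count_intra_a, r.cores.count_intra_b,
         r.cores.count_intra_a + r.cores.count_intra_b),
        ("unique_cores_exclusive", r.cores.exclusive_a, r.cores.exclusive_b,
         r.cores.union),
        ("cores_shared", "", "", r.cores.shared),
        ("scaffold_incidence_intra", r.scaffold_incidence_a,
         r.scaffold_incidence_b, r.scaffold_incidence_a + r.scaffold_incidence_b),
        ("unique_scaffolds_intra", r.scaffolds.count_intra_a,
         r.scaffolds.count_intra_b,
         r.scaffolds.count_intra_a + r.scaffolds.count_intra_b),
        ("unique_scaffolds_exclusive", r.scaffolds.exclusive_a,
         r.scaffolds.exclusive_b, r.scaffolds.union),
        ("scaffolds_shared", "", "", r.scaffolds.shared),
    ]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["measurement", "A", "B", "both"])
        w.writerows(rows)
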