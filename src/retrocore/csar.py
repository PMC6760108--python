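"""Core structure-activity relationship (CSAR) profiling.

Potency measurements (IC50) are attached to the washed molecules, and for
every core an activity distribution is aggregated over the analogs mapping
to it (n, median and mean pIC50; pIC50 = -log10 IC50 in molar).  The
annotated network condenses to a core projection in which redundant cores
(identical incident molecule sets) are dropped keeping only the largest,
and "hit-to-lead cores" — cores whose analogs concentrate high potency —
are ranked by median activity.
"""

from __future__ import annotations

import csv
import math
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .chemio import WashedMolecule
from .corenet import (
    MoleculeCoreNetwork,
    collapse_redundant_cores,
    project_core_graph,
)

__all__ = [
    "ActivityRecord",
    "CoreActivityProfile",
    "ActivityValueError",
    "to_pic50",
    "read_activity_table",
    "dedupe_activities",
    "activities_by_wid",
    "core_activity_profiles",
    "build_csar_view",
    "rank_hit_to_lead_cores",
    "write_profiles_table",
]

_UNIT_TO_MOLAR = {
    "pm": 1e-12,
    "nm": 1e-9,
    "um": 1e-6,
    "µm": 1e-6,
    "mm": 1e-3,
    "m": 1.0,
}


class ActivityValueError(ValueError):
    """Non-positive value or unknown unit; the record is rejected."""


@dataclass(frozen=True)
class ActivityRecord:
    """One reported potency measurement for a molecule."""

    source_id: str
    value: float
    units: str = "nM"
    qualifier: str = "="

    def molar(self) -> float:
        factor = _UNIT_TO_MOLAR.get(self.units.lower())
        if factor is None:
            raise ActivityValueError(f"unknown units {self.units!r}")
        if not (self.value > 0):
            raise ActivityValueError(
                f"non-positive activity value {self.value!r} for {self.source_id!r}"
            )
        return self.value * factor


def to_pic50(record: ActivityRecord | float, units: str = "nM") -> float:
    """pIC50 = -log10(IC50 in molar); 1000 nM -> 6.0."""
    if not isinstance(record, ActivityRecord):
        record = ActivityRecord(source_id="", value=float(record), units=units)
    return -math.log10(record.molar())


def read_activity_table(
    path: str | Path,
    id_column: str = "id",
    value_column: str = "value",
    units_column: str = "units",
    qualifier_column: str = "qualifier",
    default_units: str = "nM",
) -> list[ActivityRecord]:
    """Read a TSV of (molecule id, value, units, qualifier); the units and
    qualifier columns are optional (nM and "=" assumed)."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            records.append(
                ActivityRecord(
                    source_id=row[id_column].strip(),
                    value=float(row[value_column]),
                    units=(row.get(units_column) or default_units).strip(),
                    qualifier=(row.get(qualifier_column) or "=").strip(),
                )
            )
    return records


def dedupe_activities(
    records: Sequence[ActivityRecord], keep: str = "max"
) -> dict[str, ActivityRecord]:
    """One record per molecule id.

    Only exact measurements (qualifier "=") are considered.  Among
    duplicates the maximum reported value is kept by default (ChEMBL-style
    conservative de-duplication: the larger IC50 is the worse potency);
    ``keep="min"`` retains the most potent instead.
    """
    if keep not in ("max", "min"):
        raise ValueError("keep must be 'max' or 'min'")
    best: dict[str, ActivityRecord] = {}
    pick = max if keep == "max" else min
    for rec in records:
        if rec.qualifier != "=":
            continue
        rec.molar()  # validates value and units
        cur = best.get(rec.source_id)
        best[rec.source_id] = (
            rec if cur is None else pick(cur, rec, key=lambda r: r.molar())
        )
    return best


def activities_by_wid(
    molecules: Sequence[WashedMolecule],
    deduped: Mapping[str, ActivityRecord],
    keep: str = "max",
) -> dict[str, float]:
    """pIC50 per WID.  When several source ids collapsed into one washed
    structure carry activities, the duplicate rule is applied again across
    them."""
    pick = max if keep == "max" else min
    out: dict[str, float] = {}
    for mol in molecules:
        recs = [deduped[sid] for sid in mol.source_ids if sid in deduped]
        if recs:
            out[mol.wid] = to_pic50(pick(recs, key=lambda r: r.molar()))
    return out


@dataclass(frozen=True)
class CoreActivityProfile:
    """Activity distribution of one core over its annotated analogs."""

    mid: str
    canonical_smiles: str
    heavy_atoms: int
    n_analogs: int
    median_pic50: float
    mean_pic50: float
    pic50s: tuple[float, ...]


def core_activity_profiles(
    net: MoleculeCoreNetwork,
    pic50_by_wid: Mapping[str, float],
    min_analogs: int = 1,
) -> list[CoreActivityProfile]:
    """Per-core n/median/mean pIC50 over incident annotated molecules;
    cores with fewer than ``min_analogs`` annotated analogs are omitted."""
    profiles = []
    for mid in sorted(net.cores):
        values = sorted(
            pic50_by_wid[w]
            for w in net.graph.neighbors(mid)
            if w in pic50_by_wid
        )
        if len(values) < max(min_analogs, 1):
            continue
        core = net.cores[mid]
        profiles.append(
            CoreActivityProfile(
                mid=mid,
                canonical_smiles=core.canonical_smiles,
                heavy_atoms=core.heavy_atoms,
                n_analogs=len(values),
                median_pic50=statistics.median(values),
                mean_pic50=statistics.fmean(values),
                pic50s=tuple(values),
            )
        )
    return profiles


def build_csar_view(
    net: MoleculeCoreNetwork,
    profiles: Sequence[CoreActivityProfile],
    min_degree: int = 2,
) -> nx.Graph:
    """Condensed annotated core network (the final CSAR visualization data).

    Redundant cores are collapsed keeping only the largest, the survivors
    are restricted to profiled cores mapping to at least ``min_degree``
    molecules, and the core projection's edges carry shared-compound
    counts.  Node attributes: smiles, heavy_atoms, n_analogs,
    median_pic50, mean_pic50.
    """
    reduced, _ = collapse_redundant_cores(net)
    by_mid = {p.mid: p for p in profiles}
    keep = [
        mid
        for mid in reduced.cores
        if mid in by_mid and reduced.graph.degree(mid) >= min_degree
    ]
    projection = project_core_graph(reduced)
    view = projection.subgraph(keep).copy()
    for mid in view.nodes:
        p = by_mid[mid]
        view.nodes[mid].update(
            smiles=p.canonical_smiles,
            heavy_atoms=p.heavy_atoms,
            n_analogs=p.n_analogs,
            median_pic50=p.median_pic50,
            mean_pic50=p.mean_pic50,
        )
    return view


def rank_hit_to_lead_cores(
    profiles: Sequence[CoreActivityProfile], min_analogs: int = 2
) -> list[CoreActivityProfile]:
    """Cores with at least ``min_analogs`` annotated analogs, ranked by
    median pIC50 (descending; ties: more analogs, then more heavy atoms,
    then MID).  A presentation ordering, not a significance statement."""
    eligible = [p for p in profiles if p.n_analogs >= min_analogs]
    return sorted(
        eligible,
        key=lambda p: (-p.median_pic50, -p.n_analogs, -p.heavy_atoms, p.mid),
    )


def write_profiles_table(
    profiles: Sequence[CoreActivityProfile], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["mid", "core_smiles", "heavy_atoms", "n_analogs",
             "median_pic50", "mean_pic50"]
        )
        for p in profiles:
            w.writerow(
                [p.mid, p.canonical_smiles, p.heavy_atoms, p.n_analogs,
                 f"{p.median_pic50:.6g}", f"{p.mean_pic50:.6g}"]
            )
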