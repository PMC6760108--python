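"""The bipartite molecule-core network and analog-series analysis.

Molecules (U, WID-indexed) are linked to every putative core (V,
MID-indexed) they can be retrosynthetically reduced to; G = (U, V, E).
Two molecules mapped to a common core are analogs, and connected
components of G are analog series: not every pair in a series need share
a core directly, but a chain of analog relations must exist.

The module also provides the reductions used downstream: collapsing
redundant cores (identical incident molecule sets), projecting the core
graph with shared-compound edge weights, and the iterative greedy core
selection that restores a "single molecule - single scaffold" assignment
(analog-series-based scaffolds, ASBS).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from multiprocessing import get_context
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .chemio import WashedMolecule
from .fragmentation import EnumerationConfig, PutativeCore, enumerate_cores

__all__ = [
    "MoleculeCoreNetwork",
    "AnalogSeries",
    "AsbsGroup",
    "build_network",
    "find_series",
    "series_census",
    "collapse_redundant_cores",
    "project_core_graph",
    "select_asbs",
    "write_cores_table",
    "write_asw_table",
    "write_asm_table",
    "write_graphml",
]


@dataclass
class MoleculeCoreNetwork:
    """Bipartite graph G = (U, V, E) plus the WID/MID lookup tables.

    Graph nodes are WID and MID strings; molecule nodes carry
    ``bipartite=0``, core nodes ``bipartite=1``.
    """

    graph: nx.Graph
    molecules: dict[str, WashedMolecule]
    cores: dict[str, PutativeCore]
    config: EnumerationConfig

    @property
    def edges(self) -> list[tuple[str, str]]:
        """(wid, mid) membership pairs, sorted."""
        return sorted(
            (u, v) if u in self.molecules else (v, u)
            for u, v in self.graph.edges()
        )

    def core_by_smiles(self, smiles: str) -> PutativeCore | None:
        for core in self.cores.values():
            if core.canonical_smiles == smiles:
                return core
        return None

    def molecule_wids_of_core(self, mid: str) -> set[str]:
        return set(self.graph.neighbors(mid))


@dataclass
class AnalogSeries:
    """A connected component of the network: its molecules and cores, and
    (after :func:`select_asbs`) an optional single representative core."""

    asid: str
    member_wids: tuple[str, ...]
    member_mids: tuple[str, ...]
    asbs_mid: str | None = None

    @property
    def n_molecules(self) -> int:
        return len(self.member_wids)


@dataclass(frozen=True)
class AsbsGroup:
    """One molecule-disjoint group produced by greedy core selection: the
    selected scaffold core and the molecules assigned to it."""

    asbs_mid: str
    member_wids: tuple[str, ...]


def _mid_format(n: int) -> str:
    width = max(4, len(str(n)))
    return "M{:0%dd}" % width


def _enumerate_one(args) -> tuple[str, dict[str, int]]:
    wid, smiles, config = args
    return wid, enumerate_cores(smiles, config)


def build_network(
    molecules: Sequence[WashedMolecule],
    config: EnumerationConfig | None = None,
    jobs: int = 1,
) -> MoleculeCoreNetwork:
    """Fragment every molecule independently and assemble G = (U, V, E).

    Per-molecule enumeration is an independent map (parallelized over
    ``jobs`` workers); MIDs are assigned by sorted canonical core SMILES,
    so the result is identical for any worker count or chunking.
    """
    config = config or EnumerationConfig()
    tasks = [(m.wid, m.canonical_smiles, config) for m in molecules]
    if jobs > 1 and len(tasks) > 1:
        with get_context("fork").Pool(jobs) as pool:
            results = pool.map(_enumerate_one, tasks, chunksize=16)
    else:
        results = [_enumerate_one(t) for t in tasks]
    per_molecule = dict(results)

    all_cores: dict[str, int] = {}
    for cores in per_molecule.values():
        all_cores.update(cores)
    fmt = _mid_format(len(all_cores))
    mid_by_smiles = {
        smi: fmt.format(i) for i, smi in enumerate(sorted(all_cores), start=1)
    }

    graph = nx.Graph()
    mol_index = {m.wid: m for m in molecules}
    core_index = {
        mid: PutativeCore(mid=mid, canonical_smiles=smi, heavy_atoms=all_cores[smi])
        for smi, mid in mid_by_smiles.items()
    }
    graph.add_nodes_from(mol_index, bipartite=0)
    graph.add_nodes_from(core_index, bipartite=1)
    for wid, cores in per_molecule.items():
        for smi in cores:
            graph.add_edge(wid, mid_by_smiles[smi])
    return MoleculeCoreNetwork(
        graph=graph, molecules=mol_index, cores=core_index, config=config
    )


def _asid_format(n: int) -> str:
    width = max(4, len(str(n)))
    return "AS{:0%dd}" % width


def find_series(net: MoleculeCoreNetwork) -> list[AnalogSeries]:
    """Analog series = connected components of the bipartite graph.

    Singleton components (one molecule sharing no core) are retained as
    size-1 series; ordering and ASIDs follow the smallest member canonical
    SMILES of each component, so identifiers are reproducible.
    """
    components = []
    for comp in nx.connected_components(net.graph):
        wids = sorted(n for n in comp if n in net.molecules)
        mids = sorted(n for n in comp if n in net.cores)
        key = min(net.molecules[w].canonical_smiles for w in wids)
        components.append((key, wids, mids))
    components.sort(key=lambda t: t[0])
    fmt = _asid_format(len(components))
    return [
        AnalogSeries(
            asid=fmt.format(i),
            member_wids=tuple(wids),
            member_mids=tuple(mids),
        )
        for i, (_, wids, mids) in enumerate(components, start=1)
    ]


def series_census(
    series: Sequence[AnalogSeries], ks: Iterable[int] = (2, 5)
) -> dict:
    """``{"at_least": {k: number of series with >= k molecules},
    "largest": size of the largest series}``."""
    sizes = [s.n_molecules for s in series]
    return {
        "at_least": {k: sum(1 for n in sizes if n >= k) for k in sorted(ks)},
        "largest": max(sizes, default=0),
    }


def collapse_redundant_cores(
    net: MoleculeCoreNetwork,
) -> tuple[MoleculeCoreNetwork, dict[str, str]]:
    """Drop redundant cores: among cores incident to an identical molecule
    set, keep only the largest (ties: lexicographically smallest canonical
    SMILES).  Returns the reduced network and a dropped-mid -> kept-mid map.
    """
    groups: dict[frozenset, list[str]] = {}
    for mid in net.cores:
        groups.setdefault(frozenset(net.graph.neighbors(mid)), []).append(mid)
    dropped: dict[str, str] = {}
    for mids in groups.values():
        keep = min(
            mids,
            key=lambda m: (
                -net.cores[m].heavy_atoms,
                net.cores[m].canonical_smiles,
            ),
        )
        for m in mids:
            if m != keep:
                dropped[m] = keep
    graph = net.graph.copy()
    graph.remove_nodes_from(dropped)
    cores = {m: c for m, c in net.cores.items() if m not in dropped}
    return (
        MoleculeCoreNetwork(
            graph=graph, molecules=dict(net.molecules), cores=cores,
            config=net.config,
        ),
        dropped,
    )


def project_core_graph(net: MoleculeCoreNetwork) -> nx.Graph:
    """Core-core projection: an edge joins two cores sharing at least one
    molecule; edge ``weight`` counts the shared molecules."""
    return nx.bipartite.weighted_projected_graph(net.graph, list(net.cores))


def select_asbs(
    series: AnalogSeries, net: MoleculeCoreNetwork
) -> tuple[AnalogSeries, list[AsbsGroup]]:
    """Iterative greedy core selection within one series.

    Repeatedly pick the core covering the most not-yet-assigned molecules
    (ties: more heavy atoms, then lexicographically smallest canonical
    SMILES), assign those molecules to it, and continue until every
    molecule is assigned.  The groups partition the series' molecules;
    when a single core covers the whole series it is the series' ASBS
    (``asbs_mid`` set), otherwise the component admits no comprehensive
    core and splits into several single-scaffold groups.
    """
    unassigned = set(series.member_wids)
    candidates = set(series.member_mids)
    groups: list[AsbsGroup] = []
    while unassigned:
        best = min(
            candidates,
            key=lambda m: (
                -len(set(net.graph.neighbors(m)) & unassigned),
                -net.cores[m].heavy_atoms,
                net.cores[m].canonical_smiles,
            ),
        )
        covered = set(net.graph.neighbors(best)) & unassigned
        if not covered:  # pragma: no cover - whole-molecule cores prevent this
            raise RuntimeError("greedy selection stalled: uncoverable molecule")
        groups.append(AsbsGroup(asbs_mid=best, member_wids=tuple(sorted(covered))))
        unassigned -= covered
        candidates.discard(best)
    asbs = groups[0].asbs_mid if len(groups) == 1 else None
    return replace(series, asbs_mid=asbs), groups


# -- output tables (paper-style cores.tsv / ASW.tsv / ASM.tsv) --------------


def write_cores_table(net: MoleculeCoreNetwork, path: str | Path) -> None:
    """Molecule-core associations: wid, mid, core canonical SMILES."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["wid", "mid", "core_smiles"])
        for wid, mid in net.edges:
            w.writerow([wid, mid, net.cores[mid].canonical_smiles])


def write_asw_table(
    series: Sequence[AnalogSeries], path: str | Path, min_size: int = 1
) -> None:
    """Analog series - molecule associations: asid, wid."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["asid", "wid"])
        for s in series:
            if s.n_molecules < min_size:
                continue
            for wid in s.member_wids:
                w.writerow([s.asid, wid])


def write_asm_table(
    series: Sequence[AnalogSeries], path: str | Path, min_size: int = 1
) -> None:
    """Analog series - core associations: asid, mid."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["asid", "mid"])
        for s in series:
            if s.n_molecules < min_size:
                continue
            for mid in s.member_mids:
                w.writerow([s.asid, mid])


def write_graphml(net: MoleculeCoreNetwork, path: str | Path) -> None:
    """Bipartite network as GraphML with structure/size node attributes."""
    g = net.graph.copy()
    for wid, m in net.molecules.items():
        g.nodes[wid]["smiles"] = m.canonical_smiles
        g.nodes[wid]["heavy_atoms"] = m.heavy_atoms
        g.nodes[wid]["kind"] = "molecule"
    for mid, c in net.cores.items():
        g.nodes[mid]["smiles"] = c.canonical_smiles
        g.nodes[mid]["heavy_atoms"] = c.heavy_atoms
        g.nodes[mid]["kind"] = "core"
    nx.write_graphml(g, str(path))
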