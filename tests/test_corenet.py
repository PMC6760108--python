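"""Bipartite molecule-core network, series detection and ASBS selection."""

import itertools

import networkx as nx
import pytest
from rdkit import Chem

from retrocore.chemio import WashedMolecule
from retrocore.corenet import (
    MoleculeCoreNetwork,
    build_network,
    collapse_redundant_cores,
    find_series,
    project_core_graph,
    select_asbs,
    series_census,
)
from retrocore.fragmentation import EnumerationConfig, PutativeCore

CANON = Chem.CanonSmiles


def make_network(edges, heavy=None):
    """Hand-built network from (wid, mid) pairs for graph-level tests."""
    heavy = heavy or {}
    g = nx.Graph()
    mols, cores = {}, {}
    for wid, mid in edges:
        if wid not in mols:
            mols[wid] = WashedMolecule(
                wid=wid, canonical_smiles=f"mol_{wid}", heavy_atoms=10
            )
        if mid not in cores:
            cores[mid] = PutativeCore(
                mid=mid, canonical_smiles=f"core_{mid}",
                heavy_atoms=heavy.get(mid, 5),
            )
        g.add_node(wid, bipartite=0)
        g.add_node(mid, bipartite=1)
        g.add_edge(wid, mid)
    return MoleculeCoreNetwork(
        graph=g, molecules=mols, cores=cores, config=EnumerationConfig()
    )


class TestBuildNetwork:
    def test_shared_aniline_core_has_degree_two(self, anilide_network):
        molecules, net = anilide_network
        aniline = net.core_by_smiles(CANON("Nc1ccccc1"))
        assert aniline is not None
        assert net.graph.degree(aniline.mid) == 2
        # 3 distinct cores: both whole molecules + shared aniline
        assert len(net.cores) == 3

    def test_single_benzene(self, config):
        mols = [WashedMolecule("W0001", "c1ccccc1", 6)]
        net = build_network(mols, config)
        assert len(net.cores) == 1 and net.graph.number_of_edges() == 1

    def test_disjoint_chemistries_share_nothing(self, config):
        mols = [
            WashedMolecule("W0001", "c1ccccc1", 6),
            WashedMolecule("W0002", "NC1CCCCC1", 7),
        ]
        net = build_network(mols, config)
        assert nx.number_connected_components(net.graph) == 2

    def test_every_node_has_an_edge(self, small_network):
        _, net, _ = small_network
        assert all(d >= 1 for _, d in net.graph.degree())

    def test_parallel_build_identical(self, small_network, config):
        molecules, net, _ = small_network
        net4 = build_network(molecules, config, jobs=4)
        assert net.edges == net4.edges
        assert {m: c.canonical_smiles for m, c in net.cores.items()} == {
            m: c.canonical_smiles for m, c in net4.cores.items()
        }


class TestFindSeries:
    def test_two_anilides_form_one_series(self, anilide_network):
        _, net = anilide_network
        series = find_series(net)
        assert len(series) == 1
        assert series[0].n_molecules == 2

    def test_partition_property(self, small_network):
        _, net, _ = small_network
        series = find_series(net)
        all_wids = list(
            itertools.chain.from_iterable(s.member_wids for s in series)
        )
        assert sorted(all_wids) == sorted(net.molecules)
        all_mids = list(
            itertools.chain.from_iterable(s.member_mids for s in series)
        )
        assert sorted(all_mids) == sorted(net.cores)

    def test_singletons_retained(self, config):
        mols = [
            WashedMolecule("W0001", "c1ccccc1", 6),
            WashedMolecule("W0002", "c1ccncc1", 6),
        ]
        series = find_series(build_network(mols, config))
        assert [s.n_molecules for s in series] == [1, 1]


class TestCensus:
    def test_counting(self):
        mk = lambda sizes: [
            type("S", (), {"n_molecules": n})() for n in sizes
        ]
        census = series_census(mk([3, 1, 1]), ks=(2, 5))
        assert census == {"at_least": {2: 1, 5: 0}, "largest": 3}
        assert series_census([], ks=(2, 5)) == {
            "at_least": {2: 0, 5: 0}, "largest": 0
        }
        census = series_census(mk([7, 5, 2, 2, 1]), ks=(2, 5))
        assert census == {"at_least": {2: 4, 5: 2}, "largest": 7}

    def test_monotone_counts(self, small_network):
        _, net, _ = small_network
        census = series_census(find_series(net), ks=range(1, 10))
        counts = [census["at_least"][k] for k in range(1, 10)]
        assert counts == sorted(counts, reverse=True)


class TestCollapseRedundant:
    def test_largest_core_kept_per_identical_molecule_set(self):
        net = make_network(
            [("w1", "A"), ("w2", "A"), ("w1", "B"), ("w2", "B")],
            heavy={"A": 9, "B": 7},
        )
        reduced, dropped = collapse_redundant_cores(net)
        assert set(reduced.cores) == {"A"}
        assert dropped == {"B": "A"}

    def test_different_molecule_sets_both_kept(self):
        net = make_network([("w1", "A"), ("w2", "A"), ("w2", "B")])
        reduced, dropped = collapse_redundant_cores(net)
        assert set(reduced.cores) == {"A", "B"} and dropped == {}

    def test_molecule_set_structure_preserved(self, small_network):
        _, net, _ = small_network
        reduced, dropped = collapse_redundant_cores(net)
        before = {frozenset(net.graph.neighbors(m)) for m in net.cores}
        after = [frozenset(reduced.graph.neighbors(m)) for m in reduced.cores]
        assert set(after) == before  # every distinct set survives
        assert len(after) == len(before)  # exactly once
        assert set(reduced.molecules) == set(net.molecules)


class TestProjection:
    def test_shared_molecule_weight(self):
        net = make_network([("w1", "A"), ("w1", "B"), ("w2", "B")])
        proj = project_core_graph(net)
        assert proj.edges["A", "B"]["weight"] == 1
        assert not any(u == v for u, v in proj.edges())

    def test_star_fixture_weights(self):
        # comprehensive core C over {w1,w2,w3}; sub-cores with known overlap
        net = make_network(
            [("w1", "C"), ("w2", "C"), ("w3", "C"),
             ("w1", "X"), ("w2", "X"), ("w2", "Y"), ("w3", "Z")]
        )
        proj = project_core_graph(net)
        assert proj.edges["C", "X"]["weight"] == 2
        assert proj.edges["C", "Y"]["weight"] == 1
        assert proj.edges["X", "Y"]["weight"] == 1
        assert ("Y", "Z") not in proj.edges

    def test_projection_refines_components(self, small_network):
        _, net, _ = small_network
        proj = project_core_graph(net)
        series_of = {}
        for i, comp in enumerate(nx.connected_components(net.graph)):
            for n in comp:
                series_of[n] = i
        for u, v in proj.edges():
            assert series_of[u] == series_of[v]


class TestSelectAsbs:
    def test_single_comprehensive_core(self, anilide_network):
        _, net = anilide_network
        (series,) = find_series(net)
        series, groups = select_asbs(series, net)
        assert len(groups) == 1
        assert net.cores[series.asbs_mid].canonical_smiles == CANON("Nc1ccccc1")

    def test_greedy_split_chain(self):
        # X covers {w1,w2}, Y covers {w2,w3}; Y is heavier so it is picked
        # first, leaving w1 to X
        net = make_network(
            [("w1", "X"), ("w2", "X"), ("w2", "Y"), ("w3", "Y")],
            heavy={"X": 5, "Y": 8},
        )
        (series,) = find_series(net)
        series, groups = select_asbs(series, net)
        assert series.asbs_mid is None
        assert [(g.asbs_mid, g.member_wids) for g in groups] == [
            ("Y", ("w2", "w3")), ("X", ("w1",))
        ]

    def test_cover_exactly_once_and_nonincreasing(self, small_network):
        _, net, _ = small_network
        for series in find_series(net):
            _, groups = select_asbs(series, net)
            covered = list(
                itertools.chain.from_iterable(g.member_wids for g in groups)
            )
            assert sorted(covered) == sorted(series.member_wids)
            sizes = [len(g.member_wids) for g in groups]
            assert sizes == sorted(sizes, reverse=True)
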