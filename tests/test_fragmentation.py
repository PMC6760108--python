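"""Cleavage rules, single-step cleavage and putative-core enumeration."""

import pytest
from rdkit import Chem

from retrocore.chemio import heavy_atom_count
from retrocore.fragmentation import (
    BRUTEFORCE_GUARD,
    EnumerationConfig,
    MoleculeTooLargeError,
    RingBondError,
    cleave,
    default_ruleset,
    enumerate_cores,
    enumerate_cores_bruteforce,
    find_cleavage_sites,
    load_ruleset,
    save_ruleset,
)

CANON = Chem.CanonSmiles


class TestCleavageSites:
    def test_benzene_has_no_cleavable_bonds(self):
        assert find_cleavage_sites("c1ccccc1") == []

    def test_acetanilide_single_amide_bond(self):
        sites = find_cleavage_sites("CC(=O)Nc1ccccc1")
        assert len(sites) == 1
        assert sites[0].rule_names == ("amide",)
        mol = Chem.MolFromSmiles("CC(=O)Nc1ccccc1")
        bond = mol.GetBondWithIdx(sites[0].bond_index)
        atoms = {
            mol.GetAtomWithIdx(bond.GetBeginAtomIdx()).GetSymbol(),
            mol.GetAtomWithIdx(bond.GetEndAtomIdx()).GetSymbol(),
        }
        assert atoms == {"C", "N"}

    def test_diphenyl_ether_both_bonds_flagged(self):
        sites = find_cleavage_sites("c1ccccc1Oc1ccccc1")
        assert len(sites) == 2
        assert all(s.rule_names == ("ether",) for s in sites)

    def test_ring_bonds_never_matched(self):
        # lactam: the amide bond is in the ring and must not be flagged
        mol = Chem.MolFromSmiles("O=C1CCCCN1")
        for site in find_cleavage_sites(mol):
            assert not mol.GetBondWithIdx(site.bond_index).IsInRing()

    def test_urea_bond_reported_once_with_all_rules(self):
        sites = find_cleavage_sites("NC(=O)Nc1ccccc1")
        for s in sites:
            assert "urea" in s.rule_names
            assert s.rule_names == tuple(sorted(s.rule_names))

    def test_ruleset_roundtrips_through_json(self, tmp_path):
        rules = default_ruleset()
        save_ruleset(rules, tmp_path / "rules.json")
        loaded = load_ruleset(tmp_path / "rules.json")
        assert loaded.rules == rules.rules

    def test_disabling_a_rule(self):
        no_amide = default_ruleset().without("amide")
        assert find_cleavage_sites("CC(=O)Nc1ccccc1", no_amide) == []


class TestCleave:
    def test_acetanilide_fragments_and_conservation(self):
        mol = Chem.MolFromSmiles("CC(=O)Nc1ccccc1")
        (site,) = find_cleavage_sites(mol)
        big, small = cleave(mol, site.bond_index)
        assert Chem.MolToSmiles(big) == CANON("Nc1ccccc1")
        assert Chem.MolToSmiles(small) == CANON("CC=O")
        assert heavy_atom_count(big) + heavy_atom_count(small) == 10

    def test_wildcard_cap_marks_attachment_points(self):
        mol = Chem.MolFromSmiles("CC(=O)Nc1ccccc1")
        (site,) = find_cleavage_sites(mol)
        for frag in cleave(mol, site.bond_index, cap_mode="wildcard"):
            smi = Chem.MolToSmiles(frag)
            assert "[1*]" in smi or "*" in smi

    def test_ring_bond_refused(self):
        mol = Chem.MolFromSmiles("c1ccccc1")
        with pytest.raises(RingBondError):
            cleave(mol, 0)


class TestEnumerateCores:
    @pytest.mark.parametrize(
        "smiles, expected",
        [
            ("c1ccccc1", {"c1ccccc1"}),
            # aniline passes 7/10 >= 2/3, the 3-atom acyl fragment fails
            ("CC(=O)Nc1ccccc1", {"CC(=O)Nc1ccccc1", "Nc1ccccc1"}),
            # both amide fragments (8 and 7 of 15 heavy atoms) fall below 2/3
            ("O=C(Nc1ccccc1)c1ccccc1", {"O=C(Nc1ccccc1)c1ccccc1"}),
        ],
    )
    def test_worked_toy_examples(self, smiles, expected, config):
        got = set(enumerate_cores(smiles, config))
        assert got == {CANON(s) for s in expected}

    def test_heavy_atom_counts_reported(self, config):
        cores = enumerate_cores("CC(=O)Nc1ccccc1", config)
        assert cores[CANON("Nc1ccccc1")] == 7
        assert cores[CANON("CC(=O)Nc1ccccc1")] == 10

    def test_threshold_one_keeps_only_whole_molecule(self):
        cfg = EnumerationConfig(ratio_threshold=1.0)
        for smiles in ["CC(=O)Nc1ccccc1", "c1ccccc1Oc1ccccc1", "CCO"]:
            assert set(enumerate_cores(smiles, cfg)) == {CANON(smiles)}

    def test_ratio_invariant_and_whole_molecule_membership(self, config):
        for smiles in [
            "CC(=O)NCCOc1ccc(CNC(C)C)cc1",
            "CCOC(=O)c1ccc(NC(=O)CCN(C)C)cc1",
            "c1ccccc1Oc1ccccc1",
        ]:
            total = heavy_atom_count(Chem.MolFromSmiles(smiles))
            cores = enumerate_cores(smiles, config)
            assert CANON(smiles) in cores
            for heavy in cores.values():
                assert heavy + 1e-9 >= config.ratio_threshold * total

    def test_ring_can_be_a_substituent(self, config):
        # the discarded aniline part contains a ring; the surviving core
        # is the acyclic chain fragment (14/21 = 2/3)
        cores = enumerate_cores("CCCCCCCCCCCCC(=O)Nc1ccccc1", config)
        assert CANON("CCCCCCCCCCCCC=O") in cores

    def test_capping_exposes_new_cleavages(self, config):
        # after deacylation the amide N becomes an amine whose N-C bond
        # is cleavable only in the intermediate
        cores = enumerate_cores("CC(=O)NCCOc1ccc(CNC(C)C)cc1", config)
        assert CANON("CCOc1ccc(CNC(C)C)cc1") in cores

    def test_wildcard_mode_keeps_attachment(self, config):
        cfg = config.replace(cap_mode="wildcard")
        cores = set(enumerate_cores("CC(=O)Nc1ccccc1", cfg))
        assert CANON("[1*]Nc1ccccc1") in cores


class TestBruteforceOracle:
    @pytest.mark.parametrize("cap_mode", ["hydrogen", "wildcard"])
    def test_agrees_on_acetanilide(self, cap_mode):
        cfg = EnumerationConfig(cap_mode=cap_mode)
        smiles = "CC(=O)Nc1ccccc1"
        assert enumerate_cores(smiles, cfg) == enumerate_cores_bruteforce(
            smiles, cfg
        )

    def test_benzene(self, config):
        assert enumerate_cores_bruteforce("c1ccccc1", config) == {
            "c1ccccc1": 6
        }

    def test_guard_refuses_oversized_molecules(self, config):
        # polyglycine chain with > BRUTEFORCE_GUARD cleavable bonds
        smiles = "NCC(=O)" + "NCC(=O)" * BRUTEFORCE_GUARD + "O"
        with pytest.raises(MoleculeTooLargeError):
            enumerate_cores_bruteforce(smiles, config)

    @pytest.mark.parametrize("threshold", [0.5, 2.0 / 3.0, 0.8])
    def test_agreement_on_library_molecules(self, small_library, threshold):
        records, _ = small_library
        cfg = EnumerationConfig(ratio_threshold=threshold)
        for rec in records:
            smiles = CANON(rec.smiles)
            assert enumerate_cores(smiles, cfg) == enumerate_cores_bruteforce(
                smiles, cfg
            ), smiles


class TestConfig:
    def test_threshold_bounds_validated(self):
        with pytest.raises(ValueError):
            EnumerationConfig(ratio_threshold=0.0)
        with pytest.raises(ValueError):
            EnumerationConfig(ratio_threshold=1.2)

    def test_unknown_cap_mode_rejected(self):
        with pytest.raises(ValueError):
            EnumerationConfig(cap_mode="nitrogen")
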