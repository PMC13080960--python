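import warnings

import pytest

from pocketprep.cleanup import (
    OpenBabelBackend,
    SimpleGeometricBackend,
    StubProtonationBackend,
    build_residue_graph,
    compute_formal_charge,
    filter_connected_residues,
    merge,
    perceive_bonds,
    protonate,
    strip_hydrogens,
)
from pocketprep.errors import ProtonationError, ValenceError
from pocketprep.structure_io import LigandSpec, Structure, parse_mol2
from pocketprep.synthetic import make_ligand_mol2

from conftest import atom


def water(serial0: int = 1, origin=(0.0, 0.0, 0.0), res_seq: int = 1) -> Structure:
    x, y, z = origin
    return Structure(
        atoms=[
            atom(serial0, x, y, z, name="O", element="O", res_name="HOH",
                 res_seq=res_seq, record="HETATM"),
            atom(serial0 + 1, x + 0.96, y, z, name="H1", element="H",
                 res_name="HOH", res_seq=res_seq, record="HETATM"),
            atom(serial0 + 2, x - 0.24, y + 0.93, z, name="H2", element="H",
                 res_name="HOH", res_seq=res_seq, record="HETATM"),
        ],
        bonds={(serial0, serial0 + 1), (serial0, serial0 + 2)},
    )


class TestStripHydrogens:
    def test_no_hydrogens_is_identity(self, dipeptide):
        assert strip_hydrogens(dipeptide).atoms == dipeptide.atoms

    def test_water_reduces_to_oxygen(self):
        out = strip_hydrogens(water())
        assert [a.element for a in out.atoms] == ["O"]
        assert out.bonds == set()

    def test_heavy_count(self):
        atoms = [atom(i, i * 2.0, 0, 0, element="C") for i in range(1, 12)]
        atoms += [atom(i, i * 2.0, 5, 0, name=f"H{i}", element="H")
                  for i in range(12, 23)]
        out = strip_hydrogens(Structure(atoms=atoms))
        assert len(out.atoms) == 11

    def test_idempotent(self):
        s = water()
        assert strip_hydrogens(strip_hydrogens(s)).atoms == strip_hydrogens(s).atoms


class TestPerceiveBonds:
    def test_carbons_at_bond_distance(self):
        s = Structure(atoms=[atom(1, 0, 0, 0), atom(2, 1.5, 0, 0)])
        assert perceive_bonds(s).bonds == {(1, 2)}

    def test_carbons_too_far(self):
        s = Structure(atoms=[atom(1, 0, 0, 0), atom(2, 2.5, 0, 0)])
        assert perceive_bonds(s).bonds == set()

    def test_single_atom(self):
        assert perceive_bonds(Structure(atoms=[atom(1, 0, 0, 0)])).bonds == set()

    def test_unknown_element_warns(self):
        s = Structure(
            atoms=[atom(1, 0, 0, 0, element="Xx"), atom(2, 1.5, 0, 0)]
        )
        with pytest.warns(UserWarning, match="unknown element"):
            out = perceive_bonds(s)
        assert out.bonds == set()

    def test_dipeptide_graph(self, dipeptide):
        out = perceive_bonds(dipeptide)
        # N-CA-C(=O) backbone in each residue plus one peptide bond
        assert out.bonds == {(1, 2), (2, 3), (3, 4), (3, 5), (5, 6), (6, 7), (7, 8)}


class TestResidueGraph:
    def test_dipeptide(self, dipeptide):
        graph = build_residue_graph(perceive_bonds(dipeptide))
        assert len(graph.nodes) == 2 and len(graph.edges) == 1

    def test_disjoint_residues(self):
        s = Structure(atoms=[atom(1, 0, 0, 0, res_seq=1), atom(2, 9, 0, 0, res_seq=2)])
        graph = build_residue_graph(perceive_bonds(s))
        assert len(graph.nodes) == 2 and len(graph.edges) == 0

    def test_tripeptide_path(self, dipeptide):
        s = dipeptide.copy()
        # third residue linked to residue 2's carbonyl carbon at 1.33 A
        s.atoms.append(
            atom(9, 4.226 + 1.33, 2.204, 1.050, name="N", element="N",
                 res_name="GLY", res_seq=3)
        )
        graph = build_residue_graph(perceive_bonds(s))
        assert len(graph.nodes) == 3 and len(graph.edges) == 2
        degrees = sorted(graph.degree(n) for n in graph.nodes)
        assert degrees == [1, 1, 2]


class TestFilterConnectedResidues:
    def test_floating_water_dropped(self, dipeptide):
        s = dipeptide.copy()
        for a in water(serial0=100, origin=(20.0, 0.0, 0.0), res_seq=9).atoms:
            s.atoms.append(a)
        out = filter_connected_residues(perceive_bonds(strip_hydrogens(s)))
        assert {a.res_name for a in out.atoms} == {"GLY"}
        assert len(out.atoms) == 8

    def test_fully_connected_identity(self, dipeptide):
        s = perceive_bonds(dipeptide)
        assert filter_connected_residues(s).atoms == s.atoms

    def test_two_disjoint_dipeptides_all_kept(self, dipeptide):
        s = dipeptide.copy()
        far = dipeptide.copy()
        for i, a in enumerate(far.atoms):
            a.serial = 100 + i
            a.res_seq += 10
            a.x += 50.0
            s.atoms.append(a)
        out = filter_connected_residues(perceive_bonds(s))
        assert len(out.atoms) == 16

    def test_all_isolated_warns_and_empties(self):
        s = Structure(atoms=[atom(1, 0, 0, 0, res_seq=1), atom(2, 9, 0, 0, res_seq=2)])
        with pytest.warns(UserWarning, match="isolated"):
            out = filter_connected_residues(perceive_bonds(s))
        assert out.atoms == []

    def test_min_degree_invariant(self, dipeptide):
        s = dipeptide.copy()
        s.atoms.append(atom(99, 30, 0, 0, res_seq=7))
        out = filter_connected_residues(perceive_bonds(s))
        graph = build_residue_graph(out)
        assert all(graph.degree(n) >= 1 for n in graph.nodes) or not graph.nodes


class TestProtonation:
    def test_stub_contract(self, dipeptide):
        out = protonate(dipeptide, 7.4, StubProtonationBackend())
        heavy = [a for a in out.atoms if a.element != "H"]
        assert heavy == dipeptide.atoms  # heavy atoms untouched, order kept
        n_h = sum(1 for a in out.atoms if a.element == "H")
        # template: O -> 2, N -> 1; dipeptide has 2 N + 2 O
        assert n_h == 2 * 2 + 2 * 1

    def test_stub_water(self):
        o_only = strip_hydrogens(water())
        out = protonate(o_only, 7.4, StubProtonationBackend())
        assert [a.element for a in out.atoms] == ["O", "H", "H"]
        assert len(out.bonds) == 2

    def test_simple_backend_fills_valences(self, dipeptide):
        with pytest.warns(UserWarning, match="ignores pH"):
            out = protonate(dipeptide, 7.4, SimpleGeometricBackend())
        bonded = perceive_bonds(strip_hydrogens(out))
        # every heavy atom ends up saturated once its hydrogens are counted
        report = compute_formal_charge(protonate(dipeptide, 7.4, SimpleGeometricBackend()))
        assert report.total_formal_charge == 0
        assert len(bonded.atoms) == len(dipeptide.atoms)

    def test_missing_external_tool_is_actionable(self, dipeptide):
        backend = OpenBabelBackend(executable="obabel-definitely-not-here")
        with pytest.raises(ProtonationError, match="obabel-definitely-not-here"):
            protonate(dipeptide, 7.4, backend)

    def test_hydrogens_added_only_after_filtering(self, dipeptide):
        # enforced order: dehydrogenate -> bonds -> filter -> protonate
        s = dipeptide.copy()
        for a in water(serial0=100, origin=(20.0, 0.0, 0.0), res_seq=9).atoms:
            s.atoms.append(a)
        filtered = filter_connected_residues(perceive_bonds(strip_hydrogens(s)))
        out = protonate(filtered, 7.4, StubProtonationBackend())
        assert all(a.res_name != "HOH" for a in out.atoms)
        assert any(a.element == "H" for a in out.atoms)


class TestMerge:
    def test_counts_and_serials(self):
        pocket = Structure(atoms=[atom(i, i * 2.0, 0, 0) for i in range(1, 101)])
        ligand = parse_mol2(make_ligand_mol2(30))
        merged = merge(pocket, ligand)
        assert len(merged.atoms) == 130
        assert [a.serial for a in merged.atoms] == list(range(1, 131))
        assert all(a.res_name == "LIG" for a in merged.atoms[100:])

    def test_empty_pocket(self):
        ligand = parse_mol2(make_ligand_mol2(5))
        merged = merge(Structure(), ligand)
        assert len(merged.atoms) == 5

    def test_split_round_trip(self):
        pocket = Structure(atoms=[atom(i, i * 2.0, 0, 0) for i in range(1, 11)])
        ligand = parse_mol2(make_ligand_mol2(4))
        merged = merge(pocket, ligand)
        pocket_back = [a for a in merged.atoms if a.res_name != "LIG"]
        lig_back = [a for a in merged.atoms if a.res_name == "LIG"]
        assert len(pocket_back) == 10 and len(lig_back) == 4

    def test_name_collision_suffixed(self):
        pocket = Structure(atoms=[atom(1, 0, 0, 0, res_name="LIG")])
        ligand = parse_mol2(make_ligand_mol2(2))
        with pytest.warns(UserWarning, match="collides"):
            merged = merge(pocket, ligand)
        assert merged.atoms[-1].res_name == "LIG2"

    def test_atom_count_conservation(self):
        pocket = Structure(atoms=[atom(i, i * 2.0, 0, 0) for i in range(1, 8)])
        ligand = parse_mol2(make_ligand_mol2(6))
        assert len(merge(pocket, ligand).atoms) == 7 + 6


def acetate() -> Structure:
    """CH3-COO(-) with explicit hydrogens and explicit bonds."""
    atoms = [
        atom(1, 0.0, 0.0, 0.0, name="C1", element="C"),
        atom(2, 1.52, 0.0, 0.0, name="C2", element="C"),
        atom(3, 2.15, 1.05, 0.0, name="O1", element="O"),
        atom(4, 2.15, -1.05, 0.0, name="O2", element="O"),
        atom(5, -0.4, 0.5, 0.85, name="H1", element="H"),
        atom(6, -0.4, 0.5, -0.85, name="H2", element="H"),
        atom(7, -0.4, -1.0, 0.0, name="H3", element="H"),
    ]
    bonds = {(1, 2), (2, 3), (2, 4), (1, 5), (1, 6), (1, 7)}
    return Structure(atoms=atoms, bonds=bonds)


def methylammonium() -> Structure:
    atoms = [
        atom(1, 0.0, 0.0, 0.0, name="C1", element="C"),
        atom(2, 1.49, 0.0, 0.0, name="N1", element="N"),
        atom(3, -0.4, 0.5, 0.85, name="H1", element="H"),
        atom(4, -0.4, 0.5, -0.85, name="H2", element="H"),
        atom(5, -0.4, -1.0, 0.0, name="H3", element="H"),
        atom(6, 1.9, 0.5, 0.8, name="H4", element="H"),
        atom(7, 1.9, 0.5, -0.8, name="H5", element="H"),
        atom(8, 1.9, -1.0, 0.0, name="H6", element="H"),
    ]
    bonds = {(1, 2), (1, 3), (1, 4), (1, 5), (2, 6), (2, 7), (2, 8)}
    return Structure(atoms=atoms, bonds=bonds)


class TestFormalCharge:
    def test_neutral_protonated_dipeptide(self, dipeptide):
        protonated = protonate(perceive_bonds(dipeptide), 7.4,
                               SimpleGeometricBackend())
        report = compute_formal_charge(protonated)
        assert report.total_formal_charge == 0

    def test_carboxylate_minus_one(self):
        report = compute_formal_charge(acetate())
        assert report.total_formal_charge == -1

    def test_ammonium_plus_one(self):
        report = compute_formal_charge(methylammonium())
        assert report.total_formal_charge == 1

    def test_carboxylate_plus_ammonium_is_zero(self):
        s = acetate()
        for a in methylammonium().atoms:
            a.serial += 100
            a.x += 20.0
            a.res_seq = 2
            s.atoms.append(a)
        for i, j in methylammonium().bonds:
            s.bonds.add((i + 100, j + 100))
        report = compute_formal_charge(s)
        assert report.total_formal_charge == 0
        assert report.per_residue[("A", 1, " ", "ALA")] == -1
        assert report.per_residue[("A", 2, " ", "ALA")] == 1

    def test_water_neutral(self):
        assert compute_formal_charge(water()).total_formal_charge == 0

    def test_total_equals_per_residue_sum(self):
        report = compute_formal_charge(acetate())
        assert report.total_formal_charge == sum(report.per_residue.values())

    def test_order_invariance(self):
        s = acetate()
        reversed_s = Structure(atoms=list(reversed(s.atoms)), bonds=set(s.bonds))
        assert (
            compute_formal_charge(s).total_formal_charge
            == compute_formal_charge(reversed_s).total_formal_charge
        )

    def test_strict_mode_raises_on_impossible_valence(self):
        # carbon with five explicit neighbors
        atoms = [atom(1, 0, 0, 0, name="C0", element="C")]
        atoms += [atom(i, i * 1.0, 0.2, 0, name=f"H{i}", element="H")
                  for i in range(2, 7)]
        s = Structure(atoms=atoms, bonds={(1, i) for i in range(2, 7)})
        with pytest.raises(ValenceError, match=r"\[1\]"):
            compute_formal_charge(s, strict=True)
        with pytest.warns(UserWarning, match="valence"):
            report = compute_formal_charge(s)
        assert report.per_atom[1] == 0

    def test_metal_defaults_to_zero_with_warning(self):
        s = Structure(atoms=[atom(1, 0, 0, 0, name="ZN", element="Zn",
                                  res_name="ZN", record="HETATM")])
        with pytest.warns(UserWarning, match="unknown/metal"):
            report = compute_formal_charge(s)
        assert report.total_formal_charge == 0
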