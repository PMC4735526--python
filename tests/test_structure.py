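"""PDB parsing, Kabsch superposition, SASA and interface/distance measures."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from starbind.structure import (
    Atom,
    AtomSelection,
    StructureModel,
    best_dimer_rmsd,
    interface_area,
    read_pdb,
    rna_end_distance,
    sasa,
    superpose_kabsch,
)
from starbind.synthetic_structures import synthetic_kh_dimer, synthetic_rna_chain
from conftest import pdb_atom_line


def random_rigid(seed):
    rng = np.random.default_rng(seed)
    rot = Rotation.from_euler("xyz", rng.uniform(0, 360, 3), degrees=True).as_matrix()
    return rot, rng.normal(0, 10, 3)


class TestReadPdb:
    def test_two_atom_file_exact_coordinates(self, pdb_writer):
        path = pdb_writer([
            pdb_atom_line(1, "N", "ALA", "A", 1, 1.5, -2.25, 3.125, "N"),
            pdb_atom_line(2, "CA", "ALA", "A", 1, 4.0, 5.0, 6.0, "C"),
            "END",
        ])
        model = read_pdb(path)
        assert len(model) == 2
        atom = model.atoms[0]
        assert (atom.chain, atom.resseq, atom.name, atom.element) == ("A", 1, "N", "N")
        assert (atom.x, atom.y, atom.z) == (1.5, -2.25, 3.125)

    def test_altloc_a_retained_b_dropped(self, pdb_writer):
        path = pdb_writer([
            pdb_atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0, "C", altloc="A"),
            pdb_atom_line(2, "CA", "ALA", "A", 1, 1, 1, 1, "C", altloc="B"),
            pdb_atom_line(3, "CB", "ALA", "A", 1, 2, 2, 2, "C"),
            "END",
        ])
        model = read_pdb(path)
        assert len(model) == 2
        assert {a.name for a in model.atoms} == {"CA", "CB"}
        assert model.atoms[0].x == 0.0

    def test_multi_model_keeps_model_1_only(self, pdb_writer):
        path = pdb_writer([
            "MODEL        1",
            pdb_atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0, "C"),
            pdb_atom_line(2, "CA", "GLY", "A", 2, 3, 0, 0, "C"),
            "ENDMDL",
            "MODEL        2",
            pdb_atom_line(1, "CA", "GLY", "A", 1, 9, 9, 9, "C"),
            pdb_atom_line(2, "CA", "GLY", "A", 2, 9, 9, 12, "C"),
            "ENDMDL",
            "END",
        ])
        model = read_pdb(path)
        assert len(model) == 2
        assert model.atoms[0].x == 0.0

    def test_waters_excluded_by_default(self, pdb_writer):
        path = pdb_writer([
            pdb_atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0, "C"),
            pdb_atom_line(2, "O", "HOH", "A", 101, 5, 5, 5, "O", record="HETATM"),
            "END",
        ])
        assert len(read_pdb(path)) == 1
        assert len(read_pdb(path, keep_waters=True)) == 2

    def test_no_atoms_is_format_error(self, pdb_writer):
        path = pdb_writer(["REMARK nothing here", "END"])
        with pytest.raises(ValueError, match="no ATOM"):
            read_pdb(path)


class TestSuperposeKabsch:
    def test_identical_structures_zero_rmsd(self):
        m = synthetic_kh_dimer(rna=False)
        _, _, rmsd = superpose_kabsch(m, m)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_invariance(self):
        m = synthetic_kh_dimer(rna=False)
        rot, trans = random_rigid(40)
        moved = m.transformed(rot, trans)
        _, _, rmsd = superpose_kabsch(moved, m)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_recovers_transform(self):
        m = synthetic_kh_dimer(rna=False)
        rot, trans = random_rigid(41)
        moved = m.transformed(rot, trans)
        r, t, _ = superpose_kabsch(m, moved)
        assert np.allclose(r, rot, atol=1e-9)
        assert np.allclose(t, trans, atol=1e-9)

    def test_rotation_is_proper(self):
        m = synthetic_kh_dimer(rna=False)
        rot, trans = random_rigid(42)
        r, _, _ = superpose_kabsch(m.transformed(rot, trans), m)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_oracle_on_random_atoms(self):
        """RMSD equals scipy's quaternion-based optimal alignment to 1e-9."""
        rng = np.random.default_rng(43)
        for trial in range(20):
            xyz_a = rng.normal(0, 5, (10, 3))
            xyz_b = rng.normal(0, 5, (10, 3))
            atoms_a = [Atom("A", i, "", "GLY", "CA", "C", *xyz_a[i]) for i in range(10)]
            atoms_b = [Atom("A", i, "", "GLY", "CA", "C", *xyz_b[i]) for i in range(10)]
            _, _, rmsd = superpose_kabsch(
                StructureModel(atoms_a), StructureModel(atoms_b),
                AtomSelection(atom_names=None), AtomSelection(atom_names=None),
            )
            a_c = xyz_a - xyz_a.mean(0)
            b_c = xyz_b - xyz_b.mean(0)
            _, ssd = Rotation.align_vectors(b_c, a_c)
            # scipy returns the root-sum-square loss; convert to RMSD
            oracle = ssd / math.sqrt(10)
            assert rmsd == pytest.approx(oracle, abs=1e-9)

    def test_symmetry_in_arguments(self):
        m = synthetic_kh_dimer(rna=False)
        rng = np.random.default_rng(44)
        jittered = StructureModel([
            Atom(a.chain, a.resseq, a.icode, a.resname, a.name, a.element,
                 a.x + rng.normal(0, 0.5), a.y + rng.normal(0, 0.5), a.z + rng.normal(0, 0.5))
            for a in m.atoms
        ])
        _, _, r1 = superpose_kabsch(m, jittered)
        _, _, r2 = superpose_kabsch(jittered, m)
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_disordered_residues_drop_out(self):
        m = synthetic_kh_dimer(rna=False)
        # remove a residue window from the target, as if disordered
        target = m.subset(a for a in m.atoms if not (10 <= a.resseq <= 12))
        _, _, rmsd = superpose_kabsch(m, target)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_too_few_matched_atoms_is_error(self):
        atoms = [Atom("A", i, "", "GLY", "CA", "C", float(i), 0, 0) for i in range(5)]
        other = [Atom("B", i, "", "GLY", "CA", "C", float(i), 0, 0) for i in range(5)]
        with pytest.raises(ValueError, match="matched atoms"):
            superpose_kabsch(StructureModel(atoms), StructureModel(other))

    def test_dimer_chain_pairing_minimized(self):
        m = synthetic_kh_dimer(rna=False)
        # swap chain labels: only the A<->B mapping superposes exactly
        swapped = StructureModel([
            Atom({"A": "B", "B": "A"}[a.chain], a.resseq, a.icode, a.resname,
                 a.name, a.element, a.x, a.y, a.z)
            for a in m.atoms
        ])
        rmsd, mapping = best_dimer_rmsd(swapped, m, ("A", "B"), ("A", "B"))
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert mapping == {"A": "B", "B": "A"}


class TestSasa:
    def test_single_carbon_analytic_sphere(self):
        model = StructureModel([Atom("A", 1, "", "ALA", "CA", "C", 0, 0, 0)])
        total = sasa(model).sum()
        analytic = 4 * math.pi * (1.70 + 1.40) ** 2
        assert abs(total - analytic) / analytic < 0.01

    def test_distant_atoms_additive(self):
        one = StructureModel([Atom("A", 1, "", "ALA", "CA", "C", 0, 0, 0)])
        two = StructureModel([
            Atom("A", 1, "", "ALA", "CA", "C", 0, 0, 0),
            Atom("A", 2, "", "ALA", "N", "N", 100, 0, 0),
        ])
        lone_n = StructureModel([Atom("A", 2, "", "ALA", "N", "N", 100, 0, 0)])
        assert two.subset(two.atoms) and sasa(two).sum() == pytest.approx(
            sasa(one).sum() + sasa(lone_n).sum()
        )

    def test_caged_atom_buried(self):
        # central carbon enclosed by a dense shell of carbons
        shell = []
        golden = math.pi * (3 - math.sqrt(5))
        n_shell = 60
        for i in range(n_shell):
            z = 1 - 2 * (i + 0.5) / n_shell
            r = math.sqrt(1 - z * z)
            phi = golden * i
            shell.append(Atom("A", i + 2, "", "ALA", "CA", "C",
                              3.0 * r * math.cos(phi), 3.0 * r * math.sin(phi), 3.0 * z))
        model = StructureModel([Atom("A", 1, "", "ALA", "CA", "C", 0, 0, 0)] + shell)
        assert sasa(model)[0] < 1.0

    def test_convergence_in_sphere_points(self):
        m = synthetic_kh_dimer(rna=False)
        coarse = sasa(m, sphere_points=960).sum()
        fine = sasa(m, sphere_points=1920).sum()
        assert abs(fine - coarse) / fine < 0.005

    def test_unknown_element_named_in_error(self):
        model = StructureModel([Atom("A", 1, "", "HEM", "FE", "FE", 0, 0, 0)])
        with pytest.raises(ValueError, match="FE"):
            sasa(model)

    def test_cross_check_against_biotite(self):
        """Independent Shrake-Rupley implementation agrees within 2%."""
        biotite_structure = pytest.importorskip("biotite.structure")
        m = synthetic_kh_dimer(rna=False)
        arr = biotite_structure.AtomArray(len(m))
        for i, a in enumerate(m.atoms):
            arr.coord[i] = [a.x, a.y, a.z]
            arr.chain_id[i] = a.chain
            arr.res_id[i] = a.resseq
            arr.res_name[i] = a.resname
            arr.atom_name[i] = a.name
            arr.element[i] = a.element
        ref = biotite_structure.sasa(
            arr, probe_radius=1.4, point_number=960, vdw_radii="Single",
        ).sum()
        mine = sasa(m).sum()
        assert abs(mine - ref) / ref < 0.02


class TestInterfaceArea:
    def test_distant_chains_zero(self):
        atoms = [Atom("A", 1, "", "ALA", "CA", "C", 0, 0, 0),
                 Atom("B", 1, "", "ALA", "CA", "C", 100, 0, 0)]
        model = StructureModel(atoms)
        area = interface_area(model,
                              AtomSelection(chains=("A",), atom_names=None),
                              AtomSelection(chains=("B",), atom_names=None))
        assert area == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_dimer_invariant_under_group_swap(self):
        m = synthetic_kh_dimer(rna=False)
        sel_a = AtomSelection(chains=("A",), atom_names=None)
        sel_b = AtomSelection(chains=("B",), atom_names=None)
        ab = interface_area(m, sel_a, sel_b)
        ba = interface_area(m, sel_b, sel_a)
        assert ab == pytest.approx(ba, abs=1e-9)
        assert ab > 50.0  # packed helices bury a real interface

    def test_overlapping_selections_rejected(self):
        m = synthetic_kh_dimer(rna=False)
        sel = AtomSelection(chains=("A",), atom_names=None)
        with pytest.raises(ValueError, match="overlap"):
            interface_area(m, sel, sel)

    def test_nonnegative(self):
        m = synthetic_kh_dimer(rna=False, chain_gap=15.0)
        area = interface_area(m,
                              AtomSelection(chains=("A",), atom_names=None),
                              AtomSelection(chains=("B",), atom_names=None))
        assert area >= 0.0


class TestRnaEndDistance:
    def test_constructed_chains_known_distance(self):
        # chain R: one nucleotide at origin; chain S: one nucleotide 10 A away.
        r = synthetic_rna_chain("R", n_nucleotides=1, origin=(0, 0, 0))
        s = synthetic_rna_chain("S", n_nucleotides=1, origin=(0, 0, 10.0))
        model = StructureModel(r + s)
        d = rna_end_distance(model, "R", "S")
        # identical in-chain geometry: O3' -> P offset equals the origin shift
        assert d["3'(R)->5'(S)"] == pytest.approx(
            float(np.linalg.norm(np.array([4.8, 0.3, 0]) - np.array([0, 0, 10.0]))), abs=1e-9
        )

    def test_both_orderings_reported(self):
        m = synthetic_kh_dimer()
        d = rna_end_distance(m, "R", "S")
        assert set(d) == {"3'(R)->5'(S)", "3'(S)->5'(R)"}
        assert all(v > 0 for v in d.values())

    def test_same_chain_rejected(self):
        m = synthetic_kh_dimer()
        with pytest.raises(ValueError, match="distinct"):
            rna_end_distance(m, "R", "R")

    def test_missing_terminal_atom_named(self):
        atoms = [Atom("R", 1, "", "A", "C1'", "C", 0, 0, 0),
                 Atom("S", 1, "", "A", "P", "P", 5, 0, 0),
                 Atom("S", 1, "", "A", "O3'", "O", 6, 0, 0)]
        with pytest.raises(ValueError, match="O3'"):
            rna_end_distance(StructureModel(atoms), "R", "S")

    def test_antiparallel_dimer_ends_far_apart(self):
        """The synthetic dimer mimics the antiparallel arrangement: the 3' end
        of one RNA is tens of angstroms from the 5' end of the other."""
        m = synthetic_kh_dimer()
        d = rna_end_distance(m, "R", "S")
        assert min(d.values()) > 30.0
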