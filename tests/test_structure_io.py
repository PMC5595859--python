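"""Structure parsing, ligand selection, ring perception, atom typing."""

import numpy as np
import pytest

from ipscreen import (EmptyStructureError,
                      StructureParseError, build_binding_site,
                      parse_structure, perceive_aromatic_rings,
                      select_ligands)
from ipscreen.structure_io import classify_atoms

from conftest import hexagon, make_model, random_rotation


class TestParsing:
    def test_atom_count_preserved(self):
        protein = [(f"CA", "C", "GLY", 10 + i, (3.0 * i, 0, 0))
                   for i in range(8)]
        ligand = [(f"C{i}", "C", (i * 2.0, 5, 0)) for i in range(1, 5)]
        model = make_model(protein, ligand)
        assert len(model) == 12
        assert sum(a.is_hetero for a in model.atoms) == 4

    def test_altloc_highest_occupancy_wins(self):
        text = (
            "ATOM      1  CA AGLY A  10      1.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      2  CA BGLY A  10      9.000   0.000   0.000  0.40  0.00           C\n"
            "END\n")
        model = parse_structure(text, "pdb")
        assert len(model) == 1
        assert model.atoms[0].coords[0] == pytest.approx(1.0)

    def test_benzene_bonds_match_bruteforce(self):
        ligand = [(f"C{i + 1}", "C", xyz)
                  for i, xyz in enumerate(hexagon((0, 0, 0)))]
        model = make_model(ligand=ligand)
        # independent O(n^2) oracle over the covalent-radius rule
        atoms = model.atoms
        expected = set()
        for i in range(len(atoms)):
            for j in range(i + 1, len(atoms)):
                d = np.linalg.norm(atoms[i].xyz - atoms[j].xyz)
                if 0.4 < d <= 0.76 + 0.76 + 0.45:
                    expected.add((min(atoms[i].serial, atoms[j].serial),
                                  max(atoms[i].serial, atoms[j].serial)))
        assert model.bonds == expected
        assert len(model.bonds) == 6  # ring closure, no cross-ring chords

    def test_conect_supplements_inferred_bonds(self):
        text = (
            "HETATM    1  C1  LIG L   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  C2  LIG L   1       3.000   0.000   0.000  1.00  0.00           C\n"
            "CONECT    1    2\n"
            "END\n")
        model = parse_structure(text, "pdb")
        assert (1, 2) in model.bonds  # 3.0 A exceeds the distance rule

    def test_missing_file_raises(self):
        with pytest.raises(StructureParseError):
            parse_structure("/nonexistent/file.pdb", "pdb")

    def test_empty_structure_raises(self):
        with pytest.raises(EmptyStructureError):
            parse_structure("REMARK  nothing here\nEND\n", "pdb")

    def test_mmcif_round_trip_equivalent(self):
        import io

        import biotite.structure.io.pdb as bpdb
        import biotite.structure.io.pdbx as bpdbx

        from ipscreen.fixtures import FixtureSpec, build_fixture
        fx = build_fixture(FixtureSpec(patterns=frozenset("AEH")))
        arr = bpdb.PDBFile.read(io.StringIO(fx.pdb_text)).get_structure(
            model=1, extra_fields=["atom_id", "occupancy"])
        cif = bpdbx.CIFFile()
        bpdbx.set_structure(cif, arr)
        buf = io.StringIO()
        cif.write(buf)
        model = parse_structure(buf.getvalue(), "mmcif", identifier="CIF")
        ref = parse_structure(fx.pdb_text, "pdb", identifier="CIF")
        assert len(model) == len(ref)
        assert model.bonds == ref.bonds


class TestLigandSelection:
    def _model(self):
        protein = [("CA", "C", "GLY", 10, (0, 0, 0))]
        ligand = [("C1", "C", (5, 0, 0))]
        return make_model(protein, ligand)

    def test_water_always_excluded(self):
        text = (
            "HETATM    1  O   HOH L   1       0.000   0.000   0.000  1.00  0.00           O\n"
            "HETATM    2  C1  DRG M   1       5.000   0.000   0.000  1.00  0.00           C\n"
            "END\n")
        model = parse_structure(text, "pdb")
        sels = select_ligands(model)
        assert [s.component_id for s in sels] == ["DRG"]

    def test_allowlist_intersection(self):
        model = self._model()
        assert select_ligands(model, allowlist=set()) == []
        allow = {("TEST", "LIG", "L", 1)}
        assert len(select_ligands(model, allowlist=allow)) == 1

    def test_one_selection_per_instance(self):
        text = (
            "HETATM    1  C1  DRG A   5       0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  C1  DRG B   5      20.000   0.000   0.000  1.00  0.00           C\n"
            "END\n")
        sels = select_ligands(parse_structure(text, "pdb"))
        assert len(sels) == 2
        assert {s.chain for s in sels} == {"A", "B"}


class TestBindingSite:
    def _model(self, protein_offsets):
        protein = [("CA", "C", "GLY", 10 + i, (x, 0.0, 0.0))
                   for i, x in enumerate(protein_offsets)]
        ligand = [("C1", "C", (0.0, 0.0, 0.0))]
        return make_model(protein, ligand)

    def test_cutoff_contract(self):
        model = self._model([7.4, 7.6])
        site = build_binding_site(model, select_ligands(model)[0], cutoff=7.5)
        assert [a.coords[0] for a in site.protein_atoms] == pytest.approx([7.4])

    def test_empty_protein_side_allowed(self):
        model = self._model([20.0])
        site = build_binding_site(model, select_ligands(model)[0], cutoff=7.5)
        assert site.protein_atoms == []

    def test_inclusion_equals_bruteforce(self, rng):
        coords = rng.uniform(-12, 12, size=(30, 3))
        protein = [("CA", "C", "GLY", 10 + i, c) for i, c in enumerate(coords)]
        lig_coords = rng.uniform(-2, 2, size=(4, 3))
        ligand = [(f"C{i + 1}", "C", c) for i, c in enumerate(lig_coords)]
        model = make_model(protein, ligand)
        site = build_binding_site(model, select_ligands(model)[0], cutoff=7.5)
        expected = set()
        for i, c in enumerate(coords):
            dmin = min(np.linalg.norm(c - lc) for lc in lig_coords)
            if dmin <= 7.5:
                expected.add(10 + i)
        assert {a.residue_number for a in site.protein_atoms} == expected

    def test_missing_ligand_serial_raises(self):
        from ipscreen.structure_io import LigandSelection
        model = self._model([5.0])
        bad = LigandSelection("LIG", 1, "L", frozenset({999}))
        with pytest.raises(ValueError, match="missing"):
            build_binding_site(model, bad)


class TestRingPerception:
    def test_regular_hexagon(self):
        ligand = [(f"C{i + 1}", "C", xyz)
                  for i, xyz in enumerate(hexagon((2.0, 3.0, -1.0)))]
        model = make_model(ligand=ligand)
        rings = perceive_aromatic_rings(model.atoms, model.bonds)
        assert len(rings) == 1
        assert np.allclose(rings[0].centroid, (2.0, 3.0, -1.0), atol=1e-6)
        assert np.isclose(np.linalg.norm(rings[0].normal), 1.0, atol=1e-9)

    def test_puckered_ring_rejected(self):
        pts = hexagon((0, 0, 0), radius=1.53)
        for i, p in enumerate(pts):
            p[2] = 0.25 if i % 2 == 0 else -0.25  # chair conformation
        model = make_model(ligand=[(f"C{i + 1}", "C", p)
                                   for i, p in enumerate(pts)])
        rings = perceive_aromatic_rings(model.atoms, model.bonds,
                                        planarity_tolerance=0.15)
        assert rings == []

    def test_naphthalene_two_fused_rings(self):
        # two hexagons sharing the C1-C2 edge, all coplanar
        a = 1.40
        h = a * np.sqrt(3) / 2
        pts = [
            (0.0, a / 2, 0.0), (0.0, -a / 2, 0.0),          # shared edge
            (h, a, 0.0), (2 * h, a / 2, 0.0), (2 * h, -a / 2, 0.0),
            (h, -a, 0.0),
            (-h, a, 0.0), (-2 * h, a / 2, 0.0), (-2 * h, -a / 2, 0.0),
            (-h, -a, 0.0),
        ]
        model = make_model(ligand=[(f"C{i + 1}", "C", np.array(p))
                                   for i, p in enumerate(pts)])
        rings = perceive_aromatic_rings(model.atoms, model.bonds)
        assert len(rings) == 2
        shared = set(rings[0].member_serials) & set(rings[1].member_serials)
        assert len(shared) == 2
        # oracle: exhaustive chordless 6-cycle search on the bond graph
        assert self._count_hexagon_cycles(model) == 2

    @staticmethod
    def _count_hexagon_cycles(model):
        import itertools
        serials = [a.serial for a in model.atoms]
        bonds = model.bonds
        count = 0
        for combo in itertools.combinations(serials, 6):
            sub = {(a, b) for a, b in bonds if a in combo and b in combo}
            deg = {s: 0 for s in combo}
            for a, b in sub:
                deg[a] += 1
                deg[b] += 1
            if len(sub) == 6 and all(d == 2 for d in deg.values()):
                count += 1
        return count

    def test_normal_invariant_to_atom_order(self):
        pts = hexagon((0, 0, 0))
        fwd = make_model(ligand=[(f"C{i + 1}", "C", p)
                                 for i, p in enumerate(pts)])
        rev = make_model(ligand=[(f"C{i + 1}", "C", p)
                                 for i, p in enumerate(pts[::-1])])
        n1 = perceive_aromatic_rings(fwd.atoms, fwd.bonds)[0].normal
        n2 = perceive_aromatic_rings(rev.atoms, rev.bonds)[0].normal
        assert np.allclose(n1, n2, atol=1e-9)


class TestAtomClasses:
    def _classes(self, ligand):
        model = make_model(ligand=ligand)
        nm = model.neighbor_map()
        lookup = {a.serial: a for a in model.atoms}
        return classify_atoms(model.atoms, nm, lookup), model

    def test_carbonyl_oxygen_accepts_only(self):
        classes, model = self._classes([
            ("C1", "C", (0, 0, 0)), ("O1", "O", (1.23, 0, 0))])
        o = next(a.serial for a in model.atoms if a.element == "O")
        assert "hbond_acceptor" in classes[o]
        assert "hbond_donor" not in classes[o]

    def test_hydroxyl_oxygen_donates(self):
        classes, model = self._classes([
            ("C1", "C", (0, 0, 0)), ("O1", "O", (1.43, 0, 0))])
        o = next(a.serial for a in model.atoms if a.element == "O")
        assert {"hbond_donor", "hbond_acceptor"} <= classes[o]

    def test_aliphatic_carbon_hydrophobic(self):
        classes, model = self._classes([
            ("C1", "C", (0, 0, 0)), ("C2", "C", (1.53, 0, 0)),
            ("C3", "C", (-1.53, 0, 0))])
        assert all("hydrophobic" in classes[a.serial] for a in model.atoms)

    def test_carbon_next_to_oxygen_not_hydrophobic(self):
        classes, model = self._classes([
            ("C1", "C", (0, 0, 0)), ("O1", "O", (1.43, 0, 0))])
        c = next(a.serial for a in model.atoms if a.element == "C")
        assert "hydrophobic" not in classes[c]

    def test_bromine_is_halogen(self):
        classes, model = self._classes([
            ("C1", "C", (0, 0, 0)), ("BR1", "BR", (1.90, 0, 0))])
        br = next(a.serial for a in model.atoms if a.element == "BR")
        assert "halogen" in classes[br]

    def test_fluorine_excluded_by_default(self):
        classes, model = self._classes([
            ("C1", "C", (0, 0, 0)), ("F1", "F", (1.35, 0, 0))])
        f = next(a.serial for a in model.atoms if a.element == "F")
        assert "halogen" not in classes[f]

    def test_explicit_hydrogen_makes_donor(self):
        classes, model = self._classes([
            ("C1", "C", (0, 0, 0)), ("N1", "N", (1.47, 0, 0)),
            ("C2", "C", (2.2, 1.2, 0)), ("C3", "C", (2.2, -1.2, 0)),
            ("H1", "H", (1.47, 0, 1.01))])
        n = next(a.serial for a in model.atoms if a.element == "N")
        assert "hbond_donor" in classes[n]


class TestRigidMotionInvariance:
    def test_rings_classes_and_site_invariant(self, rng):
        from ipscreen.fixtures import FixtureSpec, build_fixture
        fx = build_fixture(FixtureSpec(patterns=frozenset("ABCDEFGHIJ")))
        model = parse_structure(fx.pdb_text, "pdb", identifier="REF")
        site = build_binding_site(model, select_ligands(model)[0])
        ref_rings = {r.key for r in site.ligand_rings + site.protein_rings}
        ref_classes = site.atom_classes
        ref_serials = {a.serial for a in site.protein_atoms}
        import dataclasses

        from ipscreen.structure_io import StructureModel
        for _ in range(3):
            rot = random_rotation(rng)
            shift = rng.uniform(-20, 20, size=3)
            moved = [dataclasses.replace(a, coords=tuple(rot @ a.xyz + shift))
                     for a in model.atoms]
            m2 = StructureModel("MOVED", moved, model.bonds)
            s2 = build_binding_site(m2, select_ligands(m2)[0])
            assert {r.key for r in s2.ligand_rings + s2.protein_rings} == ref_rings
            assert s2.atom_classes == ref_classes
            assert {a.serial for a in s2.protein_atoms} == ref_serials
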