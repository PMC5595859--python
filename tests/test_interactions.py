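"""Interaction detectors: geometry windows, oracles, invariances."""

import dataclasses

import numpy as np
import pytest

from ipscreen import (DetectionConfig, build_binding_site,
                      detect_hydrogen_bonds, detect_hydrophobic_contacts,
                      detect_halogen_bonds, detect_pi_stacking,
                      profile_complex, select_ligands)
from ipscreen.structure_io import StructureModel

from conftest import hexagon, make_model, random_rotation


def make_site(protein=(), ligand=(), cutoff=7.5):
    model = make_model(protein, ligand)
    return build_binding_site(model, select_ligands(model)[0], cutoff=cutoff)


class TestHydrogenBonds:
    def _site(self, da):
        # ligand amine N with a ring-side C neighbor; protein carbonyl O
        return make_site(
            protein=[("O", "O", "GLY", 10, (da, 0, 0)),
                     ("C", "C", "GLY", 10, (da + 1.23, 0, 0))],
            ligand=[("C1", "C", (-1.35, 0, 0)), ("N1", "N", (0, 0, 0))])

    def test_within_thresholds(self):
        bonds = detect_hydrogen_bonds(self._site(2.9))
        assert len(bonds) == 1
        assert bonds[0].da_distance == pytest.approx(2.9, abs=1e-3)
        assert bonds[0].ligand_is_donor

    def test_distance_cut(self):
        assert detect_hydrogen_bonds(self._site(4.5)) == []

    def test_donor_angle_cut(self):
        # acceptor on the same side as the donor's neighbor: surrogate
        # angle ~0, geometrically implausible bond rejected
        site = make_site(
            protein=[("O", "O", "GLY", 10, (-2.9, 0.2, 0)),
                     ("C", "C", "GLY", 10, (-4.13, 0.2, 0))],
            ligand=[("C1", "C", (-1.35, 0, 0)), ("N1", "N", (0, 0, 0))])
        assert detect_hydrogen_bonds(site) == []

    def test_enumeration_matches_bruteforce(self, rng):
        # 3 ligand donors x 2 protein acceptors, all mutually in range;
        # spacing keeps donors/acceptors from bonding to each other
        ligand = []
        for i in range(3):
            ligand.append((f"C{i + 1}", "C", (2.0 * i, 0, -2.97)))
            ligand.append((f"N{i + 1}", "N", (2.0 * i, 0, -1.5)))
        protein = []
        for j in range(2):
            protein.append(("O", "O", "GLY", 10 + j, (0.9 + 2.0 * j, 0.5, 0.8)))
            protein.append(("C", "C", "GLY", 10 + j, (0.9 + 2.0 * j, 1.73, 0.8)))
        site = make_site(protein, ligand)
        bonds = detect_hydrogen_bonds(site)
        # oracle: exhaustive donor x acceptor pairs within 4.1 A
        donors = [a for a in site.ligand_atoms if a.element == "N"]
        acceptors = [a for a in site.protein_atoms if a.element == "O"]
        expected = {(d.serial, a.serial) for d in donors for a in acceptors
                    if np.linalg.norm(d.xyz - a.xyz) <= 4.1}
        got = {(b.donor_serial, b.acceptor_serial) for b in bonds}
        assert got == expected
        assert len(got) == 6


class TestHydrophobicContacts:
    def _site(self, d, extra=None):
        protein = [("CD1", "C", "LEU", 10, (d, 0, 0)),
                   ("CG", "C", "LEU", 10, (d + 1.53, 0, 0))]
        if extra is not None:
            protein.append(("CD2", "C", "LEU", 10, (extra, 0.2, 0)))
        return make_site(protein=protein,
                         ligand=[("C1", "C", (0, 0, 0)),
                                 ("C2", "C", (-1.53, 0, 0))])

    def test_contact_within_range(self):
        contacts = detect_hydrophobic_contacts(self._site(3.6))
        assert [round(c.distance, 2) for c in contacts] == [3.6]

    def test_contact_beyond_range(self):
        assert detect_hydrophobic_contacts(self._site(4.2)) == []

    def test_nearest_partner_only(self):
        contacts = detect_hydrophobic_contacts(self._site(3.8, extra=3.5))
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(
            np.hypot(3.5, 0.2), abs=1e-3)


class TestPiStacking:
    def _site(self, centers, axes=None, ligand_center=(0, 0, 0)):
        axes = axes or ["z"] * len(centers)
        protein = []
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        for r, (c, ax) in enumerate(zip(centers, axes)):
            for name, xyz in zip(names, hexagon(c, axis=ax, phase=30.0)):
                protein.append((name, "C", "PHE", 10 + r, xyz))
        ligand = [(f"C{i + 1}", "C", xyz)
                  for i, xyz in enumerate(hexagon(ligand_center))]
        return make_site(protein, ligand)

    def test_parallel_stack(self):
        stacks = detect_pi_stacking(self._site([(0, 0, 3.5)]))
        assert len(stacks) == 1
        s = stacks[0]
        assert s.stack_type == "parallel"
        assert s.centroid_distance == pytest.approx(3.5, abs=1e-3)
        assert s.lateral_offset == pytest.approx(0.0, abs=1e-3)

    def test_distance_cut(self):
        assert detect_pi_stacking(self._site([(0, 0, 8.0)])) == []

    def test_offset_cut(self):
        assert detect_pi_stacking(self._site([(3.0, 0, 4.0)])) == []

    def test_opposite_faces_have_opposite_signs(self):
        stacks = detect_pi_stacking(self._site([(0, 0, 3.5), (0, 0, -3.5)]))
        assert sorted(s.face_sign for s in stacks) == [-1, 1]

    def test_tshaped_window(self):
        stacks = detect_pi_stacking(self._site([(0, 0, 4.8)], axes=["x"]))
        assert [s.stack_type for s in stacks] == ["tshaped"]
        assert stacks[0].planar_angle == pytest.approx(90.0, abs=1e-6)


class TestHalogenBonds:
    def _site(self, element="BR", donor_angle=180.0, dist=3.3):
        import math
        x = np.array([0.0, 0.0, 0.0])
        c = np.array([-1.9, 0.0, 0.0])
        a = math.radians(180.0 - donor_angle)
        acc = x + dist * np.array([math.cos(a), math.sin(a), 0.0])
        # acceptor neighbor rotated 120 deg away from the A->X direction
        ax = (x - acc) / np.linalg.norm(x - acc)
        rot = math.radians(120.0)
        w = np.array([math.cos(rot) * ax[0] - math.sin(rot) * ax[1],
                      math.sin(rot) * ax[0] + math.cos(rot) * ax[1], 0.0])
        cy = acc + 1.23 * w
        return make_site(
            protein=[("O", "O", "GLY", 10, acc), ("C", "C", "GLY", 10, cy)],
            ligand=[("C1", "C", c), (f"{element}1", element, x)])

    def test_textbook_geometry(self):
        bonds = detect_halogen_bonds(self._site(donor_angle=170.0))
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(3.3, abs=1e-3)
        assert bonds[0].donor_angle == pytest.approx(170.0, abs=0.1)

    def test_fluorine_excluded_by_default(self):
        assert detect_halogen_bonds(self._site(element="F")) == []

    def test_donor_angle_window(self):
        assert detect_halogen_bonds(self._site(donor_angle=120.0)) == []


class TestProfile:
    def test_empty_protein_side(self):
        site = make_site(protein=[("CA", "C", "GLY", 10, (30, 0, 0))],
                         ligand=[("C1", "C", (0, 0, 0))])
        p = profile_complex(site)
        assert p.n_interactions == 0

    def test_planted_census_recovered(self):
        # exactly one parallel stack and two hydrogen bonds, nothing else
        protein = [(n, "C", "PHE", 10, xyz) for n, xyz in zip(
            ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
            hexagon((0, 0, 3.5), phase=30.0))]
        protein += [("OD1", "O", "ASN", 11, (4.09, 2.9, 0)),
                    ("CG", "C", "ASN", 11, (4.09, 4.13, 0)),
                    ("NE2", "N", "GLN", 12, (-4.09, 2.9, 0)),
                    ("CD", "C", "GLN", 12, (-4.09, 4.23, 0))]
        ligand = [(f"C{i + 1}", "C", xyz)
                  for i, xyz in enumerate(hexagon((0, 0, 0)))]
        # amine N on the +x vertex direction, carbonyl O opposite
        ligand += [("N7", "N", (2.74, 0, 0)), ("O8", "O", (-2.62, 0, 0))]
        site = make_site(protein, ligand)
        p = profile_complex(site)
        assert len(p.pi_stacks) == 1
        assert len(p.hydrogen_bonds) == 2
        assert len(p.halogen_bonds) == 0
        # hydrophobic contacts only to the stacked ring (x ~ ring radius)
        assert all(c.distance > 3.0 for c in p.hydrophobic_contacts)

    def test_determinism(self):
        from ipscreen.fixtures import FixtureSpec, build_fixture
        fx = build_fixture(FixtureSpec(patterns=frozenset("ABCDEFGHIJ")))
        p1 = fx.profile
        from ipscreen import parse_structure
        model = parse_structure(fx.pdb_text, "pdb",
                                identifier=fx.structure_id)
        site = build_binding_site(model, select_ligands(model)[0])
        p2 = profile_complex(site)
        assert p1.to_json() == p2.to_json()


class TestProperties:
    @pytest.fixture
    def reference_site(self):
        from ipscreen import parse_structure
        from ipscreen.fixtures import FixtureSpec, build_fixture
        fx = build_fixture(FixtureSpec(patterns=frozenset("ABCDEFGHIJ")))
        model = parse_structure(fx.pdb_text, "pdb", identifier="REF")
        return build_binding_site(model, select_ligands(model)[0])

    def test_threshold_monotonicity(self, reference_site):
        base = DetectionConfig()
        counts = profile_complex(reference_site, base)
        wide = DetectionConfig(
            hbond_max_distance=base.hbond_max_distance + 1.0,
            hydrophobic_max_distance=base.hydrophobic_max_distance + 1.0,
            pistack_max_distance=base.pistack_max_distance + 1.0,
            halogen_max_distance=base.halogen_max_distance + 1.0)
        more = profile_complex(reference_site, wide)

        def keyset(profile):
            return ({b.sort_key for b in profile.hydrogen_bonds},
                    {s.sort_key for s in profile.pi_stacks},
                    {h.sort_key for h in profile.halogen_bonds})

        for narrow_keys, wide_keys in zip(keyset(counts), keyset(more)):
            assert narrow_keys <= wide_keys
        # hydrophobic: nearest-partner per ligand atom, so compare anchors
        assert ({c.ligand_serial for c in counts.hydrophobic_contacts}
                <= {c.ligand_serial for c in more.hydrophobic_contacts})

    def test_rigid_motion_invariance(self, reference_site, rng):
        ref = profile_complex(reference_site)

        def signature(profile):
            return (
                sorted((b.donor_serial, b.acceptor_serial,
                        round(b.da_distance, 4), round(b.donor_angle, 3))
                       for b in profile.hydrogen_bonds),
                # partner identity is unstable on exact distance ties,
                # so compare anchor + distance only
                sorted((c.ligand_serial, round(c.distance, 4))
                       for c in profile.hydrophobic_contacts),
                sorted((s.ligand_ring.member_serials, s.stack_type,
                        round(s.centroid_distance, 4),
                        round(s.lateral_offset, 4))
                       for s in profile.pi_stacks),
                sorted((h.halogen_serial, h.acceptor_serial,
                        round(h.distance, 4), round(h.donor_angle, 3))
                       for h in profile.halogen_bonds),
            )

        model_atoms = (reference_site.ligand_atoms
                       + reference_site.protein_atoms
                       + reference_site.context_atoms)
        for _ in range(3):
            rot = random_rotation(rng)
            shift = rng.uniform(-15, 15, size=3)
            moved = [dataclasses.replace(a, coords=tuple(rot @ a.xyz + shift))
                     for a in model_atoms]
            m2 = StructureModel("MOVED", moved, reference_site.bonds)
            s2 = build_binding_site(m2, select_ligands(m2)[0])
            assert signature(profile_complex(s2)) == signature(ref)
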