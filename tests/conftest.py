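"""Shared test helpers: tiny PDB builders and random-context generators."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ipscreen.fixtures import _Builder, _format_pdb
from ipscreen.interactions import (HydrogenBond, HydrophobicContact,
                                   PiStacking)
from ipscreen.patterns import BaseRingContext
from ipscreen.structure_io import AromaticRing, parse_structure


def render_pdb(builder: _Builder, structure_id: str = "TEST",
               ligand_code: str = "LIG") -> str:
    return _format_pdb(builder, structure_id, ligand_code)


def make_model(protein=(), ligand=(), structure_id="TEST"):
    """Parse a model from simple atom tuples.

    ``protein``: (name, element, resname, resnum, xyz);
    ``ligand``: (name, element, xyz) in residue LIG, chain L.
    """
    b = _Builder()
    for name, element, resname, resnum, xyz in protein:
        b.add_protein(name, element, resname, resnum, np.asarray(xyz, float))
    for name, element, xyz in ligand:
        b.add_ligand(name, element, np.asarray(xyz, float))
    return parse_structure(render_pdb(b, structure_id), "pdb",
                           identifier=structure_id)


def hexagon(center, radius=1.39, axis="z", phase=0.0):
    pts = []
    c = np.asarray(center, float)
    for k in range(6):
        a = math.radians(phase + 60.0 * k)
        if axis == "z":
            off = [radius * math.cos(a), radius * math.sin(a), 0.0]
        elif axis == "x":
            off = [0.0, radius * math.cos(a), radius * math.sin(a)]
        else:
            off = [radius * math.cos(a), 0.0, radius * math.sin(a)]
        pts.append(c + np.asarray(off))
    return pts


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


# ---------------------------------------------------------------------------
# synthetic pattern-evaluation contexts (no geometry, direct dataclasses)


def _dummy_ring(serials, owner="ligand", centroid=(0.0, 0.0, 0.0)):
    return AromaticRing(member_serials=tuple(serials), centroid=tuple(centroid),
                        normal=(0.0, 0.0, 1.0), owner=owner,
                        residue=("A", 1, "DUM"))


BASE_RING = _dummy_ring(range(1, 7))


def make_stack(ring_id, face_sign=1, stack_type="parallel", offset=0):
    return PiStacking(
        ligand_ring=BASE_RING,
        protein_ring=_dummy_ring(range(offset + 100 + 10 * ring_id,
                                       offset + 106 + 10 * ring_id),
                                 "protein"),
        centroid_distance=3.5, planar_angle=0.0 if stack_type == "parallel"
        else 85.0, lateral_offset=0.0, stack_type=stack_type,
        face_sign=face_sign)


def make_hbond(idx, ligand_is_donor=True, offset=0):
    don = offset + 10 + idx if ligand_is_donor else offset + 200 + idx
    acc = offset + 200 + idx if ligand_is_donor else offset + 10 + idx
    return HydrogenBond(donor_serial=don, acceptor_serial=acc,
                        ligand_is_donor=ligand_is_donor, da_distance=2.9,
                        donor_angle=160.0,
                        ligand_anchor_serial=don if ligand_is_donor else acc)


def make_context(n_stacks=1, face_signs=None, stack_types=None,
                 hbonds=(), hbond_vectors=(), shared_residue=False,
                 distal_h=(), distal_i=(), distal_j=(), offset=0):
    """Assemble a BaseRingContext from scalar descriptions.

    ``hbond_vectors`` are unit direction vectors per moiety bond;
    ``distal_*`` are lists of anchor-to-centroid distances x.
    """
    face_signs = face_signs or [1] * n_stacks
    stack_types = stack_types or ["parallel"] * n_stacks
    stacks = [make_stack(i, face_signs[i], stack_types[i], offset)
              for i in range(n_stacks)]
    moiety = [make_hbond(i, ld, offset) for i, ld in enumerate(hbonds)]
    vectors = {}
    for hb, v in zip(moiety, hbond_vectors):
        v = np.asarray(v, float)
        vectors[(hb.donor_serial, hb.acceptor_serial)] = tuple(
            v / np.linalg.norm(v))
    ctx = BaseRingContext(
        ring=BASE_RING, stacks=stacks, moiety_hbonds=moiety,
        distal_hydrophobic=[
            (HydrophobicContact(ligand_serial=30 + i, protein_serial=300 + i,
                                distance=3.6), x)
            for i, x in enumerate(distal_h)],
        distal_hbonds=[(make_hbond(50 + i), x)
                       for i, x in enumerate(distal_i)],
        distal_halogen=[(_dummy_halogen(i), x)
                        for i, x in enumerate(distal_j)],
        hbond_vectors=vectors)
    residues = {}
    for hb in moiety:
        prot = hb.acceptor_serial if hb.ligand_is_donor else hb.donor_serial
        residues[prot] = ("A", 5 + offset, "GLN") if shared_residue \
            else ("A", 5 + prot, "GLN")
    ctx._protein_residues = residues
    return ctx


def _dummy_halogen(i):
    from ipscreen.interactions import HalogenBond
    return HalogenBond(halogen_serial=40 + i, acceptor_serial=400 + i,
                       distance=3.3, donor_angle=170.0, acceptor_angle=120.0)


def random_context(rng: np.random.Generator, offset: int = 0) -> BaseRingContext:
    """A random but structurally valid evaluation context (>=1 stack)."""
    n_stacks = int(rng.integers(1, 4))
    face_signs = [int(rng.choice([-1, 1])) for _ in range(n_stacks)]
    stack_types = [str(rng.choice(["parallel", "tshaped"]))
                   for _ in range(n_stacks)]
    n_hb = int(rng.integers(0, 4))
    hbonds = [bool(rng.integers(0, 2)) for _ in range(n_hb)]
    vectors = rng.normal(size=(n_hb, 3))
    return make_context(
        n_stacks=n_stacks, face_signs=face_signs, stack_types=stack_types,
        hbonds=hbonds, hbond_vectors=list(vectors), offset=offset,
        shared_residue=bool(rng.integers(0, 2)),
        distal_h=list(rng.uniform(1.0, 9.0, size=rng.integers(0, 3))),
        distal_i=list(rng.uniform(1.0, 9.0, size=rng.integers(0, 3))),
        distal_j=list(rng.uniform(1.0, 12.0, size=rng.integers(0, 3))))


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)
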