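"""Synthetic binding-site fixtures in PDB format.

Generates small, fully deterministic protein-ligand complexes that
realize any requested implication-closed subset of the interaction
patterns A-J.  The ligand is a planar six-membered carbon ring with
substituent arms; protein partners are written as plausible standard
residues (PHE rings for stacking, GLN/ASN amide donors and acceptors,
LEU carbons for hydrophobic probes, a backbone-style carbonyl for the
halogen acceptor) so that atom typing is exercised realistically.

The fixtures are geometric test articles, not synthesizable molecules.
Every generated structure is self-checked: it is parsed, profiled and
pattern-evaluated through the package's own pipeline and must evaluate
to exactly the requested pattern set.

Geometry summary (ligand ring centered at the origin in the z=0 plane):

* stacking partners sit 3.2-5.4 A above/below the ring, parallel or
  perpendicular depending on which of B, C, D are requested;
* paired hydrogen-bond sites (E-G) are exocyclic amine/carbonyl groups
  on adjacent ring vertices with in-plane protein partners at 2.9 A,
  bond axes antiparallel when G is requested and perpendicular when not;
* distal probes extend along separate ring directions, with anchors at
  the band midpoints (5.25 A hydrophobic, 5.75 A hydrogen bond, 8.5 A
  halogen) when the pattern is requested and at least 0.5 A outside the
  band when it is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .interactions import InteractionProfile, profile_complex
from .patterns import (PATTERN_IMPLICATIONS, PatternEvaluation,
                       best_evaluation, closed_pattern_subsets,
                       is_implication_closed)
from .structure_io import build_binding_site, parse_structure, select_ligands

__all__ = [
    "FixtureSpec",
    "FixtureResult",
    "FixtureConstraintError",
    "build_fixture",
    "fixture_library",
]

_RING_R = 1.39  # ligand ring radius (benzene-like)


class FixtureConstraintError(ValueError):
    """Requested pattern set violates an implication or is unconstructible."""


@dataclass(frozen=True)
class FixtureSpec:
    """Request for one synthetic fixture."""

    patterns: frozenset[str]
    stack_distance: float = 3.5
    hbond_length: float = 2.9
    #: distal anchor placements (band midpoints)
    distal_hydrophobic: float = 5.25
    distal_hbond: float = 5.75
    distal_halogen: float = 8.5
    seed: int = 0
    #: identifier written into the fixture header / file name stem
    structure_id: str = "FIXTURE"
    #: chemical component code of the ligand (max 3 characters)
    ligand_code: str = "LIG"

    def __post_init__(self):
        if not 1 <= len(self.ligand_code) <= 3:
            raise FixtureConstraintError(
                f"ligand_code must be 1-3 characters: {self.ligand_code!r}")
        bad = set(self.patterns) - set("ABCDEFGHIJ")
        if bad:
            raise FixtureConstraintError(f"unknown patterns: {sorted(bad)}")
        for p in sorted(self.patterns):
            if p == "A":
                continue
            req = PATTERN_IMPLICATIONS[p]
            if req not in self.patterns:
                raise FixtureConstraintError(
                    f"pattern set {sorted(self.patterns)} violates "
                    f"implication {p} => {req}")


@dataclass
class FixtureResult:
    """A generated fixture with its self-checked ground truth."""

    spec: FixtureSpec
    pdb_text: str
    expected_patterns: frozenset[str]
    expected_count: int
    profile: InteractionProfile
    evaluation: PatternEvaluation

    @property
    def structure_id(self) -> str:
        return self.spec.structure_id


def _unit(az_deg: float) -> np.ndarray:
    a = math.radians(az_deg)
    return np.array([math.cos(a), math.sin(a), 0.0])


def _hexagon(center: np.ndarray, radius: float, normal_axis: str = "z",
             phase_deg: float = 0.0) -> list[np.ndarray]:
    pts = []
    for k in range(6):
        a = math.radians(phase_deg + 60.0 * k)
        if normal_axis == "z":
            off = np.array([radius * math.cos(a), radius * math.sin(a), 0.0])
        elif normal_axis == "x":  # ring in the yz plane
            off = np.array([0.0, radius * math.cos(a), radius * math.sin(a)])
        else:  # normal along y: ring in the xz plane
            off = np.array([radius * math.cos(a), 0.0, radius * math.sin(a)])
        pts.append(center + off)
    return pts


_PHE_NAMES = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")


class _Builder:
    def __init__(self):
        self.protein: list[tuple] = []  # (name, element, resname, resnum, xyz)
        self.ligand: list[tuple] = []   # (name, element, xyz)
        self._res = 9

    def next_res(self) -> int:
        self._res += 1
        return self._res

    def add_protein_ring(self, center, normal_axis="z", phase=0.0):
        resnum = self.next_res()
        for name, xyz in zip(_PHE_NAMES,
                             _hexagon(center, _RING_R, normal_axis, phase)):
            self.protein.append((name, "C", "PHE", resnum, xyz))
        return resnum

    def add_protein(self, name, element, resname, resnum, xyz):
        self.protein.append((name, element, resname, resnum, np.asarray(xyz)))

    def add_ligand(self, name, element, xyz):
        self.ligand.append((name, element, np.asarray(xyz)))


def _place_stacks(b: _Builder, s: frozenset[str], zstack: float) -> None:
    if "A" not in s:
        return
    if "B" not in s:
        # single parallel stack
        b.add_protein_ring(np.array([0.0, 0.0, zstack]), "z", phase=30.0)
    elif {"C", "D"} <= s:
        b.add_protein_ring(np.array([0.0, 0.0, zstack]), "z", phase=30.0)
        b.add_protein_ring(np.array([0.0, 0.0, -zstack]), "z", phase=30.0)
    elif "C" in s:
        # parallel above, T-shaped (perpendicular) below
        b.add_protein_ring(np.array([0.0, 0.0, zstack]), "z", phase=30.0)
        b.add_protein_ring(np.array([0.0, 0.0, -4.8]), "x")
    elif "D" in s:
        # two parallel stacks on the same face, vertically separated so
        # that no spurious covalent bonds are inferred between them
        b.add_protein_ring(np.array([0.0, 0.0, 3.2]), "z", phase=30.0)
        b.add_protein_ring(np.array([0.0, 0.0, 5.4]), "z", phase=30.0)
    else:
        # B alone: two T-shaped stacks on the same face, laterally split
        b.add_protein_ring(np.array([-1.0, 0.0, 4.8]), "x")
        b.add_protein_ring(np.array([1.0, 0.0, 4.8]), "x")


def _place_hbond_sites(b: _Builder, s: frozenset[str], d_hb: float) -> None:
    """Exocyclic amine (donor) and carbonyl (acceptor) moiety sites."""
    if "E" not in s:
        return
    u1 = _unit(60.0)
    u2 = _unit(120.0)
    # ligand amine N bonded to the azimuth-60 ring vertex
    n_d = u1 * (_RING_R + 1.35)
    b.add_ligand("N7", "N", n_d)
    # ligand carbonyl O double-bonded to the azimuth-120 ring vertex
    o_a = u2 * (_RING_R + 1.23)
    b.add_ligand("O8", "O", o_a)

    y = np.array([0.0, 1.0, 0.0])
    # protein acceptor: carbonyl O above the ligand amine, axis +y
    o_p = n_d + d_hb * y
    c_p = o_p + 1.23 * y
    # protein donor: amide N near the ligand carbonyl
    if "G" in s:
        # bond axis antiparallel to the first bond: donor straight above
        n_p = o_a + d_hb * y
        c_n = n_p + 1.33 * y
    else:
        # bond axis perpendicular: donor displaced along -x
        n_p = o_a - d_hb * np.array([1.0, 0.0, 0.0])
        c_n = n_p - 1.33 * np.array([1.0, 0.0, 0.0])
    if "F" in s:
        res = b.next_res()
        b.add_protein("OE1", "O", "GLN", res, o_p)
        b.add_protein("CD", "C", "GLN", res, c_p)
        b.add_protein("NE2", "N", "GLN", res, n_p)
        b.add_protein("CG", "C", "GLN", res, c_n)
    else:
        r1 = b.next_res()
        b.add_protein("OD1", "O", "ASN", r1, o_p)
        b.add_protein("CG", "C", "ASN", r1, c_p)
        r2 = b.next_res()
        b.add_protein("NE2", "N", "GLN", r2, n_p)
        b.add_protein("CD", "C", "GLN", r2, c_n)


def _place_distal_probes(b: _Builder, s: frozenset[str],
                         xh: float, xi: float, xj: float,
                         d_hb: float) -> None:
    # hydrophobic arm along azimuth 300
    u = _unit(300.0)
    anchor = xh if "H" in s else 3.4
    chain = [2.70, 3.95] if "H" in s else [2.45]
    for k, r in enumerate(chain):
        b.add_ligand(f"C{9 + k}", "C", u * r)
    b.add_ligand("C11", "C", u * anchor)
    res = b.next_res()
    b.add_protein("CD1", "C", "LEU", res, u * (anchor + 3.6))
    b.add_protein("CG", "C", "LEU", res, u * (anchor + 5.1))

    # hydrogen-bond arm along azimuth 0
    u = _unit(0.0)
    anchor = xi if "I" in s else 4.8
    chain = [2.85, 4.30] if "I" in s else [2.53, 3.66]
    for k, r in enumerate(chain):
        b.add_ligand(f"C{12 + k}", "C", u * r)
    b.add_ligand("O14", "O", u * anchor)
    res = b.next_res()
    b.add_protein("ND2", "N", "ASN", res, u * (anchor + d_hb))
    b.add_protein("CG", "C", "ASN", res, u * (anchor + d_hb + 1.33))

    # halogen arm along azimuth 240
    u = _unit(240.0)
    anchor = xj if "J" in s else 7.2
    chain = ([2.84, 4.29, 5.74, 7.19] if "J" in s else [2.84, 4.29, 5.70])
    for k, r in enumerate(chain):
        b.add_ligand(f"C{15 + k}", "C", u * r)
    b.add_ligand("BR1", "BR", u * anchor)
    o_x = u * (anchor + 3.3)
    # carbonyl carbon placed so the Y-A...X acceptor angle is 120 deg
    w = _rotate_z(-u, 120.0)
    res = b.next_res()
    b.add_protein("O", "O", "GLY", res, o_x)
    b.add_protein("C", "C", "GLY", res, o_x + 1.23 * w)


def _rotate_z(v: np.ndarray, deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], v[2]])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _format_pdb(b: _Builder, structure_id: str,
                ligand_code: str = "LIG", transform=None) -> str:
    def xf(xyz):
        if transform is None:
            return xyz
        rot, trans = transform
        return rot @ xyz + trans

    def fmt(record, serial, name, element, resname, chain, resnum, xyz):
        x, y, z = xf(xyz)
        # wwPDB v3.3 fixed columns; single-letter elements have their
        # atom name starting in column 14
        aname = f" {name:<3}" if len(element) == 1 else f"{name:<4}"
        return (f"{record:<6}{serial:>5} {aname} {resname:>3} {chain}"
                f"{resnum:>4}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {element:>2}")

    lines = [f"HEADER    SYNTHETIC FIXTURE                       {structure_id:<10}"]
    serial = 0
    for name, element, resname, resnum, xyz in b.protein:
        serial += 1
        lines.append(fmt("ATOM", serial, name, element, resname, "A",
                         resnum, xyz))
    for name, element, xyz in b.ligand:
        serial += 1
        lines.append(fmt("HETATM", serial, name, element, ligand_code, "L", 1, xyz))
    lines.append("END")
    return "\n".join(lines) + "\n"


def build_fixture(spec: FixtureSpec,
                  config: RunConfig | None = None,
                  jitter: float = 0.0,
                  transform: bool = False,
                  self_check: bool = True) -> FixtureResult:
    """Build one fixture realizing exactly the requested pattern set.

    The generated structure is parsed, profiled and evaluated through
    the normal pipeline; construction fails with
    :class:`FixtureConstraintError` if the evaluation does not
    reproduce the requested set exactly.

    Parameters
    ----------
    jitter
        Maximum radial displacement (A) applied to the distal anchors.
        Values up to 0.2 A keep every anchor at least 0.1 A inside (or
        0.4 A outside) its band.
    transform
        Apply a seeded random rigid motion to all coordinates.
    """
    cfg = config or RunConfig()
    s = frozenset(spec.patterns)
    if s and not is_implication_closed(s):  # defensive; spec validates too
        raise FixtureConstraintError(f"set {sorted(s)} not implication-closed")

    rng = np.random.default_rng(spec.seed)
    jit = lambda: float(rng.uniform(-jitter, jitter)) if jitter else 0.0

    b = _Builder()
    # ligand base ring: planar carbon hexagon in the z=0 plane
    for k, xyz in enumerate(_hexagon(np.zeros(3), _RING_R, "z")):
        b.add_ligand(f"C{k + 1}", "C", xyz)

    if "A" in s:
        _place_stacks(b, s, spec.stack_distance)
        _place_hbond_sites(b, s, spec.hbond_length)
        _place_distal_probes(
            b, s,
            spec.distal_hydrophobic + jit(),
            spec.distal_hbond + jit(),
            spec.distal_halogen + jit(),
            spec.hbond_length)
    else:
        # pattern-free fixture: bare ring plus one distant protein atom
        b.add_protein("CA", "C", "GLY", b.next_res(),
                      np.array([0.0, 0.0, 8.95]))

    xform = None
    if transform:
        xform = (_random_rotation(rng), rng.uniform(-5.0, 5.0, size=3))
    text = _format_pdb(b, spec.structure_id, spec.ligand_code, xform)

    model = parse_structure(text, "pdb", identifier=spec.structure_id)
    ligands = select_ligands(model)
    if len(ligands) != 1:
        raise FixtureConstraintError(
            f"fixture must contain one ligand, found {len(ligands)}")
    site = build_binding_site(model, ligands[0],
                              cutoff=cfg.detection.binding_site_cutoff,
                              config=cfg.detection)
    profile = profile_complex(site, cfg.detection)
    evaluation = best_evaluation(profile, cfg.patterns)

    if self_check and evaluation.pattern_set != s:
        raise FixtureConstraintError(
            f"self-check failed for {sorted(s)}: evaluated to "
            f"{sorted(evaluation.pattern_set)}")

    return FixtureResult(
        spec=spec, pdb_text=text, expected_patterns=s,
        expected_count=len(s), profile=profile, evaluation=evaluation)


_B36 = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _ligand_code(k: int) -> str:
    """Distinct 3-character component code per library index."""
    return "L" + _B36[(k // 36) % 36] + _B36[k % 36]


def fixture_library(n: int, seed: int = 0,
                    config: RunConfig | None = None,
                    jitter: float = 0.2,
                    transform: bool = True) -> list[FixtureResult]:
    """Generate ``n`` fixtures cycling through all closed pattern subsets.

    Deterministic for a given seed: fixture ``k`` realizes the ``k``-th
    closed subset (cyclically), with jittered distal placements and a
    random rigid motion derived from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    subsets = closed_pattern_subsets(include_empty=True)
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        s = subsets[k % len(subsets)]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        label = "".join(sorted(s)) or "NONE"
        spec = FixtureSpec(
            patterns=s, seed=sub_seed,
            structure_id=f"FX{k:04d}_{label}",
            ligand_code=_ligand_code(k))
        out.append(build_fixture(spec, config=config, jitter=jitter,
                                 transform=transform))
    return out
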