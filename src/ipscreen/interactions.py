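"""Detection of noncovalent protein-ligand interactions.

Four interaction types are detected across the ligand-protein
interface of a binding-site complex: hydrogen bonds, hydrophobic
contacts, pi-stacking and halogen bonds.  Geometric thresholds follow
the documented defaults of the reference profiler (PLIP) and are
configurable through :class:`~ipscreen.config.DetectionConfig`.

All detectors operate on heavy atoms.  Hydrogen-bond donor angles use
explicit hydrogens when present and fall back to a heavy-neighbor
surrogate angle otherwise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .config import DetectionConfig
from .structure_io import AromaticRing, BindingSiteComplex

__all__ = [
    "HydrogenBond",
    "HydrophobicContact",
    "PiStacking",
    "HalogenBond",
    "InteractionProfile",
    "detect_hydrogen_bonds",
    "detect_hydrophobic_contacts",
    "detect_pi_stacking",
    "detect_halogen_bonds",
    "profile_complex",
]


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, in degrees."""
    v1 = a - b
    v2 = c - b
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        return 0.0
    cosv = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosv)))


def vector_angle(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle between two direction vectors in degrees, in [0, 180]."""
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        return 0.0
    cosv = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosv)))


@dataclass(frozen=True)
class HydrogenBond:
    donor_serial: int
    acceptor_serial: int
    ligand_is_donor: bool
    da_distance: float
    donor_angle: float
    ligand_anchor_serial: int

    @property
    def sort_key(self):
        lig = self.ligand_anchor_serial
        prot = self.acceptor_serial if self.ligand_is_donor else self.donor_serial
        return (lig, prot)


@dataclass(frozen=True)
class HydrophobicContact:
    ligand_serial: int
    protein_serial: int
    distance: float

    @property
    def sort_key(self):
        return (self.ligand_serial, self.protein_serial)


@dataclass(frozen=True)
class PiStacking:
    ligand_ring: AromaticRing
    protein_ring: AromaticRing
    centroid_distance: float
    planar_angle: float
    lateral_offset: float
    stack_type: str  # "parallel" | "tshaped"
    face_sign: int   # +1 | -1: side of the ligand-ring plane

    @property
    def sort_key(self):
        return (self.ligand_ring.member_serials, self.protein_ring.member_serials)


@dataclass(frozen=True)
class HalogenBond:
    halogen_serial: int
    acceptor_serial: int
    distance: float
    donor_angle: float
    acceptor_angle: float

    @property
    def sort_key(self):
        return (self.halogen_serial, self.acceptor_serial)


@dataclass
class InteractionProfile:
    """All detected interactions for one binding-site complex."""

    structure_id: str
    ligand_id: str
    hydrogen_bonds: list[HydrogenBond] = field(default_factory=list)
    hydrophobic_contacts: list[HydrophobicContact] = field(default_factory=list)
    pi_stacks: list[PiStacking] = field(default_factory=list)
    halogen_bonds: list[HalogenBond] = field(default_factory=list)
    config: DetectionConfig = field(default_factory=DetectionConfig)
    complex: BindingSiteComplex | None = None

    @property
    def n_interactions(self) -> int:
        return (len(self.hydrogen_bonds) + len(self.hydrophobic_contacts)
                + len(self.pi_stacks) + len(self.halogen_bonds))

    def to_dict(self) -> dict:
        def ring_d(r: AromaticRing) -> dict:
            return {"members": list(r.member_serials), "owner": r.owner,
                    "residue": list(r.residue)}
        return {
            "structure_id": self.structure_id,
            "ligand_id": self.ligand_id,
            "hydrogen_bonds": [asdict(h) for h in self.hydrogen_bonds],
            "hydrophobic_contacts": [asdict(h) for h in self.hydrophobic_contacts],
            "pi_stacks": [{
                "ligand_ring": ring_d(s.ligand_ring),
                "protein_ring": ring_d(s.protein_ring),
                "centroid_distance": s.centroid_distance,
                "planar_angle": s.planar_angle,
                "lateral_offset": s.lateral_offset,
                "stack_type": s.stack_type,
                "face_sign": s.face_sign,
            } for s in self.pi_stacks],
            "halogen_bonds": [asdict(h) for h in self.halogen_bonds],
            "config": asdict(self.config),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# hydrogen bonds


def _donor_angle(site: BindingSiteComplex, donor_serial: int,
                 acceptor_xyz: np.ndarray) -> tuple[float, bool]:
    """Best donor angle and whether an explicit hydrogen supplied it.

    With explicit hydrogens bonded to the donor the angle is the largest
    D-H...A angle at the hydrogen.  Without hydrogens the surrogate is
    the smallest heavy-neighbor-D...A angle at the donor (collinear
    approach to the lone-pair side scores 180).  Donors with no heavy
    neighbors (e.g. water oxygen) trivially pass with 180.
    """
    donor = site.atom(donor_serial)
    nbrs = [site.atom(s) for s in site.neighbor_map().get(donor_serial, [])]
    hydrogens = [n for n in nbrs if n.element.upper() == "H"]
    if hydrogens:
        best = max(_angle(donor.xyz, h.xyz, acceptor_xyz) for h in hydrogens)
        return best, True
    heavy = [n for n in nbrs if n.element.upper() != "H"]
    if not heavy:
        return 180.0, False
    worst = min(_angle(n.xyz, donor.xyz, acceptor_xyz) for n in heavy)
    return worst, False


def detect_hydrogen_bonds(site: BindingSiteComplex,
                          config: DetectionConfig | None = None,
                          ) -> list[HydrogenBond]:
    """Enumerate interface hydrogen bonds.

    All ligand-donor/protein-acceptor and protein-donor/ligand-acceptor
    pairs with heavy-atom D-A distance at most the configured maximum
    and a qualifying donor angle are reported.  When both directions
    qualify for the same atom pair, only one bond is kept (ligand-donor
    direction preferred).
    """
    cfg = config or DetectionConfig()
    classes = site.atom_classes
    lig = site.ligand_atoms
    prot = site.protein_atoms

    def donors(atoms):
        return [a for a in atoms if "hbond_donor" in classes.get(a.serial, ())]

    def acceptors(atoms):
        return [a for a in atoms if "hbond_acceptor" in classes.get(a.serial, ())]

    found: dict[tuple[int, int], HydrogenBond] = {}

    def consider(donor, acceptor, ligand_is_donor: bool):
        d = float(np.linalg.norm(donor.xyz - acceptor.xyz))
        if d > cfg.hbond_max_distance:
            return
        angle, from_h = _donor_angle(site, donor.serial, acceptor.xyz)
        min_angle = cfg.hbond_min_angle if from_h else cfg.hbond_min_angle_noh
        if angle < min_angle:
            return
        pair = (min(donor.serial, acceptor.serial),
                max(donor.serial, acceptor.serial))
        anchor = donor.serial if ligand_is_donor else acceptor.serial
        bond = HydrogenBond(
            donor_serial=donor.serial, acceptor_serial=acceptor.serial,
            ligand_is_donor=ligand_is_donor, da_distance=d,
            donor_angle=angle, ligand_anchor_serial=anchor)
        prev = found.get(pair)
        if prev is None or (ligand_is_donor and not prev.ligand_is_donor):
            found[pair] = bond

    for dnr in donors(lig):
        for acc in acceptors(prot):
            consider(dnr, acc, True)
    for dnr in donors(prot):
        for acc in acceptors(lig):
            consider(dnr, acc, False)

    return sorted(found.values(), key=lambda h: h.sort_key)


# ---------------------------------------------------------------------------
# hydrophobic contacts


def detect_hydrophobic_contacts(site: BindingSiteComplex,
                                config: DetectionConfig | None = None,
                                ) -> list[HydrophobicContact]:
    """Hydrophobic carbon-carbon contacts across the interface.

    For every hydrophobic ligand carbon, only the nearest hydrophobic
    protein partner within the distance threshold is kept; this curbs
    contact inflation in tightly packed apolar pockets.
    """
    cfg = config or DetectionConfig()
    classes = site.atom_classes
    lig = [a for a in site.ligand_atoms
           if "hydrophobic" in classes.get(a.serial, ())]
    prot = [a for a in site.protein_atoms
            if "hydrophobic" in classes.get(a.serial, ())]
    out = []
    for la in lig:
        best = None
        for pa in prot:
            d = float(np.linalg.norm(la.xyz - pa.xyz))
            if d > cfg.hydrophobic_max_distance:
                continue
            if best is None or d < best[0] or (d == best[0]
                                               and pa.serial < best[1].serial):
                best = (d, pa)
        if best is not None:
            out.append(HydrophobicContact(
                ligand_serial=la.serial, protein_serial=best[1].serial,
                distance=best[0]))
    return sorted(out, key=lambda c: c.sort_key)


# ---------------------------------------------------------------------------
# pi-stacking


def detect_pi_stacking(site: BindingSiteComplex,
                       config: DetectionConfig | None = None,
                       ) -> list[PiStacking]:
    """Parallel and T-shaped ring stacks across the interface.

    Geometry per candidate ligand-ring/protein-ring pair: centroid
    distance, interplanar angle (folded into [0, 90]) and lateral offset
    (in-plane component of the centroid displacement with respect to
    the ligand-ring plane).  ``face_sign`` records which side of the
    ligand-ring plane holds the protein-ring centroid, measured along
    the canonicalized ligand-ring normal.
    """
    cfg = config or DetectionConfig()
    t_lo, t_hi = cfg.pistack_tshaped_angle_range
    out = []
    for lr in site.ligand_rings:
        lc = lr.centroid_xyz
        ln = lr.normal_xyz
        for pr in site.protein_rings:
            delta = pr.centroid_xyz - lc
            d = float(np.linalg.norm(delta))
            if d > cfg.pistack_max_distance or d < 1e-9:
                continue
            ang = vector_angle(ln, pr.normal_xyz)
            if ang > 90.0:
                ang = 180.0 - ang
            axial = float(np.dot(delta, ln))
            offset = float(np.linalg.norm(delta - axial * ln))
            if offset > cfg.pistack_max_offset:
                continue
            if ang <= cfg.pistack_parallel_max_angle:
                stype = "parallel"
            elif t_lo <= ang <= t_hi:
                stype = "tshaped"
            else:
                continue
            if abs(axial) < 1e-9:
                continue  # centroid exactly in-plane: no face
            out.append(PiStacking(
                ligand_ring=lr, protein_ring=pr, centroid_distance=d,
                planar_angle=ang, lateral_offset=offset, stack_type=stype,
                face_sign=1 if axial > 0 else -1))
    return sorted(out, key=lambda s: s.sort_key)


# ---------------------------------------------------------------------------
# halogen bonds


def detect_halogen_bonds(site: BindingSiteComplex,
                         config: DetectionConfig | None = None,
                         ) -> list[HalogenBond]:
    """Ligand halogen to protein O/N/S halogen bonds.

    Requires a carbon neighbor on the halogen (the sigma-hole lies on
    the C-X axis): the C-X...A angle must fall within the donor window
    and, when the acceptor has heavy neighbors, at least one
    Y-A...X angle must fall within the acceptor window.
    """
    cfg = config or DetectionConfig()
    classes = site.atom_classes
    nm = site.neighbor_map()
    halogens = [a for a in site.ligand_atoms
                if "halogen" in classes.get(a.serial, ())]
    acceptors = [a for a in site.protein_atoms
                 if a.element.upper() in ("O", "N", "S")]
    d_lo = cfg.halogen_donor_angle - cfg.halogen_donor_tolerance
    d_hi = cfg.halogen_donor_angle + cfg.halogen_donor_tolerance
    a_lo = cfg.halogen_acceptor_angle - cfg.halogen_acceptor_tolerance
    a_hi = cfg.halogen_acceptor_angle + cfg.halogen_acceptor_tolerance
    out = []
    for x in halogens:
        carbons = [site.atom(s) for s in nm.get(x.serial, [])
                   if site.atom(s).element.upper() == "C"]
        if not carbons:
            continue
        cx = carbons[0]
        for acc in acceptors:
            d = float(np.linalg.norm(x.xyz - acc.xyz))
            if d > cfg.halogen_max_distance:
                continue
            don_ang = _angle(cx.xyz, x.xyz, acc.xyz)
            if not d_lo <= don_ang <= d_hi:
                continue
            ynbrs = [site.atom(s) for s in nm.get(acc.serial, [])
                     if site.atom(s).element.upper() != "H"]
            if ynbrs:
                acc_angles = [_angle(y.xyz, acc.xyz, x.xyz) for y in ynbrs]
                ok = [a for a in acc_angles if a_lo <= a <= a_hi]
                if not ok:
                    continue
                acc_ang = ok[0]
            else:
                acc_ang = 180.0
            out.append(HalogenBond(
                halogen_serial=x.serial, acceptor_serial=acc.serial,
                distance=d, donor_angle=don_ang, acceptor_angle=acc_ang))
    return sorted(out, key=lambda h: h.sort_key)


# ---------------------------------------------------------------------------


def profile_complex(site: BindingSiteComplex,
                    config: DetectionConfig | None = None,
                    ) -> InteractionProfile:
    """Run all four detectors on a binding-site complex."""
    cfg = config or DetectionConfig()
    return InteractionProfile(
        structure_id=site.structure_id,
        ligand_id=site.ligand.instance_id,
        hydrogen_bonds=detect_hydrogen_bonds(site, cfg),
        hydrophobic_contacts=detect_hydrophobic_contacts(site, cfg),
        pi_stacks=detect_pi_stacking(site, cfg),
        halogen_bonds=detect_halogen_bonds(site, cfg),
        config=cfg,
        complex=site,
    )
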