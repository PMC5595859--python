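"""Structure parsing and binding-site preparation.

Reads protein-ligand complexes from PDB or mmCIF files, identifies
hetero ligand instances, carves binding-site complexes around them,
perceives aromatic rings on both sides of the interface, and classifies
heavy atoms by their interaction capability (hydrogen-bond donor /
acceptor, hydrophobic, halogen).

The whole pipeline operates on heavy atoms: explicit hydrogens are used
when present but never required.  Donor capability is inferred from
element, connectivity and bond-length heuristics when hydrogens are
absent, which is the common situation for X-ray entries.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .config import DetectionConfig

__all__ = [
    "AtomRecord",
    "StructureModel",
    "LigandSelection",
    "AromaticRing",
    "BindingSiteComplex",
    "StructureParseError",
    "EmptyStructureError",
    "parse_structure",
    "select_ligands",
    "load_allowlist",
    "build_binding_site",
    "perceive_aromatic_rings",
    "classify_atoms",
]

#: single-bond covalent radii in Angstrom (Cordero et al. consensus values)
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "NA": 1.66, "MG": 1.41, "SI": 1.11, "P": 1.07, "S": 1.05, "CL": 1.02,
    "K": 2.03, "CA": 1.76, "MN": 1.39, "FE": 1.32, "CO": 1.26, "NI": 1.24,
    "CU": 1.32, "ZN": 1.22, "SE": 1.20, "BR": 1.20, "I": 1.39,
}
_DEFAULT_RADIUS = 0.77

#: residue names treated as water
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: elements that may be members of an aromatic ring
AROMATIC_ELEMENTS = frozenset({"C", "N", "O", "S"})

#: halogen-bond capable elements (F handled by configuration)
HALOGEN_ELEMENTS = frozenset({"CL", "BR", "I"})


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


class EmptyStructureError(StructureParseError):
    """Raised when a parsed structure contains no atoms."""


@dataclass(frozen=True, slots=True)
class AtomRecord:
    """One heavy (or hydrogen) atom with residue bookkeeping."""

    serial: int
    name: str
    element: str
    coords: tuple[float, float, float]
    residue_name: str
    residue_number: int
    chain: str
    is_hetero: bool
    altloc: str = ""

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_number, self.residue_name)


class StructureModel:
    """A parsed structure: atoms plus inferred covalent bonds.

    Bonds are stored as unordered serial pairs.  They are inferred from
    interatomic distances (sum of covalent radii plus slack) and
    supplemented by CONECT records where available.
    """

    def __init__(self, identifier: str, atoms: list[AtomRecord],
                 bonds: set[tuple[int, int]] | None = None):
        self.identifier = identifier
        self.atoms = list(atoms)
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serials in model")
        self._by_serial = {a.serial: a for a in self.atoms}
        self.bonds: set[tuple[int, int]] = set()
        if bonds:
            for a, b in bonds:
                self.add_bond(a, b)

    def __len__(self) -> int:
        return len(self.atoms)

    def atom(self, serial: int) -> AtomRecord:
        return self._by_serial[serial]

    def has_atom(self, serial: int) -> bool:
        return serial in self._by_serial

    def add_bond(self, a: int, b: int) -> None:
        if a == b:
            raise ValueError(f"self-bond on serial {a}")
        if a not in self._by_serial or b not in self._by_serial:
            raise ValueError(f"bond ({a}, {b}) references missing atom")
        self.bonds.add((min(a, b), max(a, b)))

    def neighbors(self, serial: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == serial:
                out.append(b)
            elif b == serial:
                out.append(a)
        return sorted(out)

    def neighbor_map(self) -> dict[int, list[int]]:
        nm: dict[int, list[int]] = {a.serial: [] for a in self.atoms}
        for a, b in self.bonds:
            nm[a].append(b)
            nm[b].append(a)
        for v in nm.values():
            v.sort()
        return nm

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class LigandSelection:
    """One hetero residue instance selected as a ligand."""

    component_id: str
    residue_number: int
    chain: str
    atom_serials: frozenset[int]

    def __post_init__(self):
        if not self.atom_serials:
            raise ValueError("empty ligand selection")

    @property
    def instance_id(self) -> str:
        return f"{self.component_id}:{self.chain}:{self.residue_number}"


@dataclass(frozen=True)
class AromaticRing:
    """A planar 5- or 6-membered ring of aromatic-capable atoms."""

    member_serials: tuple[int, ...]
    centroid: tuple[float, float, float]
    normal: tuple[float, float, float]
    owner: str  # "ligand" | "protein"
    residue: tuple[str, int, str]

    @property
    def centroid_xyz(self) -> np.ndarray:
        return np.asarray(self.centroid, dtype=float)

    @property
    def normal_xyz(self) -> np.ndarray:
        return np.asarray(self.normal, dtype=float)

    @property
    def size(self) -> int:
        return len(self.member_serials)

    @property
    def key(self) -> tuple:
        return (self.owner,) + tuple(sorted(self.member_serials))


@dataclass
class BindingSiteComplex:
    """One ligand instance plus the protein atoms around it."""

    structure_id: str
    ligand: LigandSelection
    ligand_atoms: list[AtomRecord]
    protein_atoms: list[AtomRecord]
    ligand_rings: list[AromaticRing]
    protein_rings: list[AromaticRing]
    atom_classes: dict[int, frozenset[str]]
    bonds: set[tuple[int, int]] = field(default_factory=set)
    #: protein atoms pulled in solely to complete rings / neighbor lookups
    context_atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, serial: int) -> AtomRecord:
        return self._index()[serial]

    def _index(self) -> dict[int, AtomRecord]:
        if not hasattr(self, "_atom_index"):
            idx = {}
            for a in self.ligand_atoms + self.protein_atoms + self.context_atoms:
                idx[a.serial] = a
            self._atom_index = idx
        return self._atom_index

    def neighbor_map(self) -> dict[int, list[int]]:
        if not hasattr(self, "_nbr"):
            nm: dict[int, list[int]] = {s: [] for s in self._index()}
            for a, b in self.bonds:
                if a in nm and b in nm:
                    nm[a].append(b)
                    nm[b].append(a)
            for v in nm.values():
                v.sort()
            self._nbr = nm
        return self._nbr


# ---------------------------------------------------------------------------
# parsing


def _radius(element: str) -> float:
    return COVALENT_RADII.get(element.upper(), _DEFAULT_RADIUS)


def infer_bonds(atoms: list[AtomRecord], slack: float = 0.45) -> set[tuple[int, int]]:
    """Infer covalent bonds by the covalent-radius distance rule.

    Two atoms are bonded when their distance is at most the sum of their
    covalent radii plus ``slack`` (and above 0.4 A, to guard against
    corrupt coordinates).
    """
    if len(atoms) < 2:
        return set()
    coords = np.array([a.coords for a in atoms])
    radii = np.array([_radius(a.element) for a in atoms])
    tree = cKDTree(coords)
    max_cut = 2.0 * radii.max() + slack
    bonds: set[tuple[int, int]] = set()
    for i, j in tree.query_pairs(max_cut):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if 0.4 < d <= radii[i] + radii[j] + slack:
            si, sj = atoms[i].serial, atoms[j].serial
            bonds.add((min(si, sj), max(si, sj)))
    return bonds


def _read_conect(text: str) -> set[tuple[int, int]]:
    bonds = set()
    for line in text.splitlines():
        if not line.startswith("CONECT"):
            continue
        fields = [line[6:11]] + [line[11 + 5 * k: 16 + 5 * k] for k in range(4)]
        try:
            serials = [int(f) for f in fields if f.strip()]
        except ValueError:
            continue
        if len(serials) >= 2:
            a = serials[0]
            for b in serials[1:]:
                if a != b:
                    bonds.add((min(a, b), max(a, b)))
    return bonds


def parse_structure(source, fmt: str = "pdb", *,
                    identifier: str | None = None,
                    bond_slack: float = 0.45) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model of multi-model files is used.  Alternate
    locations are resolved to the highest-occupancy conformer (ties keep
    the first, i.e. altloc ``A`` in conventionally ordered files).
    Covalent bonds are inferred from interatomic distances and, for PDB
    input, supplemented by CONECT records.

    Parameters
    ----------
    source
        Path to a structure file, or the file content as text.
    fmt
        ``"pdb"`` or ``"mmcif"``.
    """
    import biotite.structure.io.pdb as bpdb
    import biotite.structure.io.pdbx as bpdbx

    fmt = fmt.lower()
    if fmt not in ("pdb", "mmcif", "cif"):
        raise StructureParseError(f"unsupported format: {fmt!r}")

    is_path = isinstance(source, (str, os.PathLike)) and (
        not str(source).lstrip().startswith(("ATOM", "HETATM", "HEADER",
                                             "REMARK", "CRYST", "MODEL",
                                             "data_", "#")))
    if is_path and not os.path.exists(source):
        raise StructureParseError(f"cannot read structure file: {source}")
    if is_path:
        with open(source) as fh:
            text = fh.read()
        default_id = os.path.splitext(os.path.basename(str(source)))[0]
    else:
        text = str(source)
        default_id = "structure"

    try:
        if fmt == "pdb":
            pfile = bpdb.PDBFile.read(io.StringIO(text))
            array = pfile.get_structure(
                model=1, altloc="occupancy",
                extra_fields=["atom_id", "occupancy"])
        else:
            cfile = bpdbx.CIFFile.read(io.StringIO(text))
            array = bpdbx.get_structure(
                cfile, model=1, altloc="occupancy",
                extra_fields=["atom_id", "occupancy"])
    except Exception as exc:  # noqa: BLE001 - normalise library errors
        if fmt == "pdb" and not any(
                ln.startswith(("ATOM", "HETATM")) for ln in text.splitlines()):
            raise EmptyStructureError("structure contains no atoms") from exc
        raise StructureParseError(f"failed to parse structure: {exc}") from exc

    if array.array_length() == 0:
        raise EmptyStructureError("structure contains no atoms")

    atoms = []
    for i in range(array.array_length()):
        element = str(array.element[i]).strip()
        if not element:
            element = str(array.atom_name[i]).strip()[:1]
        atoms.append(AtomRecord(
            serial=int(array.atom_id[i]),
            name=str(array.atom_name[i]).strip(),
            element=element.upper() if len(element) > 1 else element.upper(),
            coords=tuple(float(c) for c in array.coord[i]),
            residue_name=str(array.res_name[i]).strip(),
            residue_number=int(array.res_id[i]),
            chain=str(array.chain_id[i]).strip(),
            is_hetero=bool(array.hetero[i]),
        ))

    bonds = infer_bonds(atoms, slack=bond_slack)
    if fmt == "pdb":
        present = {a.serial for a in atoms}
        for a, b in _read_conect(text):
            if a in present and b in present:
                bonds.add((a, b))
    return StructureModel(identifier or default_id, atoms, bonds)


# ---------------------------------------------------------------------------
# ligand selection


def load_allowlist(path) -> set[tuple[str, str, str, int]]:
    """Load a biological-relevance allowlist.

    The file is a TSV with columns ``structure_id``, ``component_id``,
    ``chain``, ``residue_number`` (header optional).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = [c.lower() for c in df.columns]
    expected = ["structure_id", "component_id", "chain", "residue_number"]
    if cols != expected:
        # headerless file: reread assuming positional columns
        df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                         names=expected, comment="#")
    out = set()
    for row in df.itertuples(index=False):
        out.add((str(row.structure_id).strip(), str(row.component_id).strip(),
                 str(row.chain).strip(), int(row.residue_number)))
    return out


def select_ligands(model: StructureModel,
                   exclusion: frozenset[str] | set[str] = frozenset(),
                   allowlist: set[tuple[str, str, str, int]] | None = None,
                   ) -> list[LigandSelection]:
    """Identify ligand instances: hetero residues that are not water.

    Residues whose component code is in ``exclusion`` are dropped.  When
    an ``allowlist`` of ``(structure_id, component_id, chain,
    residue_number)`` tuples is given, only listed instances survive
    (the biological-relevance decision is delegated entirely to it).
    One selection is returned per residue instance.
    """
    excl = {e.upper() for e in exclusion} | WATER_NAMES
    groups: dict[tuple[str, int, str], list[int]] = {}
    for a in model.atoms:
        if not a.is_hetero:
            continue
        if a.residue_name.upper() in excl:
            continue
        groups.setdefault(a.residue_key, []).append(a.serial)
    out = []
    for (chain, resnum, resname), serials in sorted(groups.items()):
        if allowlist is not None:
            if (model.identifier, resname, chain, resnum) not in allowlist:
                continue
        out.append(LigandSelection(
            component_id=resname, residue_number=resnum, chain=chain,
            atom_serials=frozenset(serials)))
    return out


# ---------------------------------------------------------------------------
# aromatic ring perception


def _plane_fit(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-fit plane: returns (centroid, unit normal, max deviation)."""
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    # normal = eigenvector of the smallest covariance eigenvalue
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    dev = float(np.abs(centered @ normal).max())
    return centroid, normal, dev


def _canonical_normal(normal: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Fix the sign of a plane normal: positive z, ties broken by +x, +y."""
    for axis in (2, 0, 1):
        if normal[axis] > tol:
            return normal
        if normal[axis] < -tol:
            return -normal
    return normal


def _order_cycle(members: list[int], nbrs: dict[int, list[int]]) -> list[int] | None:
    """Order a chordless cycle's node set along the ring path."""
    member_set = set(members)
    start = min(members)
    order = [start]
    prev = None
    cur = start
    while True:
        nxt = [n for n in nbrs[cur] if n in member_set and n != prev]
        if not nxt:
            return None
        # deterministic walk direction
        step = min(nxt)
        if step == start:
            return order if len(order) == len(members) else None
        if step in order:
            return None
        order.append(step)
        prev, cur = cur, step
        if len(order) > len(members):
            return None


def perceive_aromatic_rings(atoms: list[AtomRecord],
                            bonds: set[tuple[int, int]],
                            owner: str = "ligand",
                            planarity_tolerance: float = 0.15,
                            ) -> list[AromaticRing]:
    """Find planar 5/6-membered rings of aromatic-capable elements.

    The bond graph restricted to C/N/O/S atoms is searched for its
    minimum cycle basis; cycles of size 5 or 6 whose members deviate
    from their best-fit plane by at most ``planarity_tolerance`` are
    reported.  The ring normal is the unit eigenvector of the smallest
    covariance eigenvalue, sign-canonicalized (positive z component,
    ties broken toward +x).
    """
    candidates = {a.serial: a for a in atoms
                  if a.element.upper() in AROMATIC_ELEMENTS}
    g = nx.Graph()
    g.add_nodes_from(candidates)
    for a, b in bonds:
        if a in candidates and b in candidates:
            g.add_edge(a, b)
    rings = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_edges() < sub.number_of_nodes():
            continue
        for cycle in nx.minimum_cycle_basis(sub):
            if not 5 <= len(cycle) <= 6:
                continue
            nbrs = {n: sorted(sub.neighbors(n)) for n in cycle}
            order = _order_cycle(sorted(cycle), nbrs)
            if order is None:
                continue
            coords = np.array([candidates[s].coords for s in order])
            centroid, normal, dev = _plane_fit(coords)
            if dev > planarity_tolerance:
                continue
            normal = _canonical_normal(normal)
            normal = normal / np.linalg.norm(normal)
            first = candidates[order[0]]
            rings.append(AromaticRing(
                member_serials=tuple(order),
                centroid=tuple(float(c) for c in centroid),
                normal=tuple(float(c) for c in normal),
                owner=owner,
                residue=first.residue_key,
            ))
    rings.sort(key=lambda r: r.member_serials)
    return rings


# ---------------------------------------------------------------------------
# atom classification


def classify_atoms(atoms: list[AtomRecord],
                   neighbor_map: dict[int, list[int]],
                   atom_lookup: dict[int, AtomRecord],
                   ring_members: frozenset[int] = frozenset(),
                   fluorine_donates: bool = False,
                   ) -> dict[int, frozenset[str]]:
    """Assign interaction-capability classes to heavy atoms.

    Classes are ``hbond_donor``, ``hbond_acceptor``, ``hydrophobic`` and
    ``halogen``.  When explicit hydrogens are present they decide donor
    status; otherwise donors are inferred from element, connectivity and
    a carbonyl bond-length heuristic:

    * O with one heavy neighbor: carbonyl-like (C=O below 1.30 A) is an
      acceptor only; longer single bonds are hydroxyl-like and donate.
    * O with two heavy neighbors (ether/ester): acceptor only.
    * N inside an aromatic ring with two heavy neighbors and no explicit
      H: pyridine-like acceptor.  Non-ring N with at most two heavy
      neighbors: donor (an attachable hydrogen is implied).
    * hydrophobic: carbon whose heavy neighbors are all carbon.
    * halogen: Cl, Br, I (optionally F).
    """
    classes: dict[int, frozenset[str]] = {}
    for a in atoms:
        el = a.element.upper()
        tags: set[str] = set()
        nbr_serials = neighbor_map.get(a.serial, [])
        heavy = [atom_lookup[s] for s in nbr_serials
                 if s in atom_lookup and atom_lookup[s].element.upper() != "H"]
        has_h = any(s in atom_lookup and atom_lookup[s].element.upper() == "H"
                    for s in nbr_serials)
        if el == "O":
            tags.add("hbond_acceptor")
            if has_h:
                tags.add("hbond_donor")
            elif len(heavy) == 0:
                tags.add("hbond_donor")  # water-like
            elif len(heavy) == 1:
                d = float(np.linalg.norm(a.xyz - heavy[0].xyz))
                if d >= 1.30:
                    tags.add("hbond_donor")  # hydroxyl-like single bond
        elif el == "N":
            in_ring = a.serial in ring_members
            if has_h:
                tags.add("hbond_donor")
            elif in_ring and len(heavy) == 2:
                tags.add("hbond_acceptor")  # pyridine-like
            elif not in_ring and len(heavy) <= 2:
                tags.add("hbond_donor")
                if len(heavy) == 1:
                    d = float(np.linalg.norm(a.xyz - heavy[0].xyz))
                    if d < 1.25:  # nitrile / imine-like
                        tags.add("hbond_acceptor")
                        tags.discard("hbond_donor")
        elif el == "C":
            if all(n.element.upper() in ("C", "H") for n in heavy):
                tags.add("hydrophobic")
        if el in HALOGEN_ELEMENTS or (fluorine_donates and el == "F"):
            tags.add("halogen")
        classes[a.serial] = frozenset(tags)
    return classes


# ---------------------------------------------------------------------------
# binding-site carving


def build_binding_site(model: StructureModel, ligand: LigandSelection,
                       cutoff: float = 7.5,
                       config: DetectionConfig | None = None,
                       ) -> BindingSiteComplex:
    """Carve the binding site of one ligand instance.

    Protein (non-hetero) atoms whose minimum distance to any ligand atom
    is at most ``cutoff`` form the site.  Aromatic rings are perceived
    on the ligand and on the protein side (ring perception considers
    complete residues so rings straddling the cutoff are not truncated),
    and interaction-capability classes are assigned.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    cfg = config or DetectionConfig(binding_site_cutoff=cutoff)
    missing = [s for s in ligand.atom_serials if not model.has_atom(s)]
    if missing:
        raise ValueError(f"ligand serials missing from model: {sorted(missing)}")

    ligand_atoms = sorted((model.atom(s) for s in ligand.atom_serials),
                          key=lambda a: a.serial)
    lig_coords = np.array([a.coords for a in ligand_atoms])

    protein_all = [a for a in model.atoms
                   if not a.is_hetero and a.serial not in ligand.atom_serials]
    protein_atoms: list[AtomRecord] = []
    if protein_all:
        tree = cKDTree(lig_coords)
        pc = np.array([a.coords for a in protein_all])
        dmin, _ = tree.query(pc, k=1)
        protein_atoms = [a for a, d in zip(protein_all, dmin) if d <= cutoff]

    # complete residues for ring perception and neighbor geometry
    site_residues = {a.residue_key for a in protein_atoms}
    in_site = {a.serial for a in protein_atoms}
    context = [a for a in protein_all
               if a.residue_key in site_residues and a.serial not in in_site]

    relevant = ligand_atoms + protein_atoms + context
    rel_serials = {a.serial for a in relevant}
    bonds = {(a, b) for a, b in model.bonds
             if a in rel_serials and b in rel_serials}

    lig_rings = perceive_aromatic_rings(
        ligand_atoms, bonds, owner="ligand",
        planarity_tolerance=cfg.ring_planarity_tolerance)
    prot_rings = perceive_aromatic_rings(
        protein_atoms + context, bonds, owner="protein",
        planarity_tolerance=cfg.ring_planarity_tolerance)
    # keep only protein rings that touch the carved site
    prot_rings = [r for r in prot_rings
                  if any(s in in_site for s in r.member_serials)]

    nm: dict[int, list[int]] = {s: [] for s in rel_serials}
    for a, b in bonds:
        nm[a].append(b)
        nm[b].append(a)
    lookup = {a.serial: a for a in relevant}
    ring_members = frozenset(s for r in lig_rings + prot_rings
                             for s in r.member_serials)
    classes = classify_atoms(
        relevant, nm, lookup, ring_members=ring_members,
        fluorine_donates=cfg.fluorine_donates)

    return BindingSiteComplex(
        structure_id=model.identifier,
        ligand=ligand,
        ligand_atoms=ligand_atoms,
        protein_atoms=sorted(protein_atoms, key=lambda a: a.serial),
        ligand_rings=lig_rings,
        protein_rings=prot_rings,
        atom_classes=classes,
        bonds=bonds,
        context_atoms=sorted(context, key=lambda a: a.serial),
    )
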