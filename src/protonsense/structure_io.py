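"""Read/write PDB structures, select chains and ions, superpose, define the membrane plane.

The receptors studied here are seven-transmembrane proteins; analyses that
compare residues across receptors require every structure to sit in a common
reference frame (classically, superposed onto bovine rhodopsin 1F88 chain A)
and need an explicit membrane mid-plane to decide which residues are
extracellular.  This module supplies that plumbing: a thin atom-record model
on top of gemmi's PDB parser, rigid-body superposition over paired Cα atoms,
and an oriented plane through three anchor Cα atoms.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a parsed structure (PDB ATOM or HETATM record)."""

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    position: np.ndarray  # shape (3,), Å
    element: str
    is_hetero: bool
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial} has invalid position {self.position!r}")
        object.__setattr__(self, "position", pos)

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class StructureModel:
    """Atoms of a single protein chain, plus identifying labels.

    ``structure_id`` identifies the structure (e.g. PDB code + chain);
    ``gene_label`` identifies the receptor gene, which downstream consensus
    analysis uses to remove redundant contributions from the same gene.
    """

    structure_id: str
    gene_label: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms])

    def ca_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.atom_name == "CA" and not a.is_hetero]

    def residues(self) -> dict[tuple[str, int, str], list[AtomRecord]]:
        """Atoms grouped by residue, in order of first appearance.

        Insertion codes sort lexicographically after the residue number.
        """
        groups: dict[tuple[str, int, str], list[AtomRecord]] = {}
        for atom in self.atoms:
            groups.setdefault(atom.residue_key, []).append(atom)
        return dict(
            sorted(groups.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2]))
        )

    def find_ca(self, residue_number: int) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == "CA" and a.residue_number == residue_number and not a.is_hetero:
                return a
        return None

    def hetero_positions(self, element: str) -> np.ndarray:
        """Positions of HETATM atoms of the given element (e.g. 'NA' for Na+)."""
        pos = [a.position for a in self.atoms if a.is_hetero and a.element.upper() == element.upper()]
        return np.array(pos) if pos else np.zeros((0, 3))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        rot = np.asarray(rotation, float)
        tr = np.asarray(translation, float)
        new_atoms = [replace(a, position=rot @ a.position + tr) for a in self.atoms]
        return StructureModel(self.structure_id, self.gene_label, new_atoms)


@dataclass(frozen=True)
class MembranePlane:
    """Plane through three anchor Cα atoms, oriented toward the extracellular side.

    signed_height(x) = dot(unit_normal, x) - offset; positive heights are
    extracellular.
    """

    anchor_points: np.ndarray  # (3, 3)
    unit_normal: np.ndarray  # (3,)
    offset: float

    def __post_init__(self):
        n = np.asarray(self.unit_normal, float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("unit_normal must have unit length")
        anchors = np.asarray(self.anchor_points, float)
        if anchors.shape != (3, 3):
            raise ValueError("exactly three anchor points required")
        heights = anchors @ n - self.offset
        if np.max(np.abs(heights)) > 1e-6:
            raise ValueError("anchor points must lie on the plane")
        object.__setattr__(self, "anchor_points", anchors)
        object.__setattr__(self, "unit_normal", n)

    def signed_height(self, point: np.ndarray) -> float:
        return float(np.dot(self.unit_normal, np.asarray(point, float)) - self.offset)


def parse_pdb(path: str | os.PathLike, chain: str) -> StructureModel:
    """Parse one chain of a PDB file into a :class:`StructureModel`.

    HETATM records (ions, ligands) of the chain are retained with
    ``is_hetero=True``.  Alternate locations are resolved to the highest
    occupancy; ties go to the lexicographically first altLoc identifier.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    structure = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
    structure.setup_entities()
    if len(structure) == 0:
        raise ValueError(f"{path}: no models in file")
    model = structure[0]

    atoms: list[AtomRecord] = []
    for ch in model:
        if ch.name != chain:
            continue
        for residue in ch:
            is_het = residue.het_flag == "H"
            # resolve altlocs per atom name
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in residue:
                by_name.setdefault(atom.name, []).append(atom)
            for name, variants in by_name.items():
                chosen = min(variants, key=lambda a: (-a.occ, a.altloc or "A"))
                atoms.append(
                    AtomRecord(
                        serial=chosen.serial,
                        atom_name=name,
                        residue_name=residue.name,
                        chain_id=ch.name,
                        residue_number=residue.seqid.num,
                        insertion_code=(residue.seqid.icode or " ").strip() or " ",
                        position=np.array([chosen.pos.x, chosen.pos.y, chosen.pos.z]),
                        element=chosen.element.name.upper(),
                        is_hetero=is_het,
                        occupancy=chosen.occ,
                        b_factor=chosen.b_iso,
                    )
                )
    if not atoms:
        raise ValueError(f"{path}: no atoms for chain {chain!r}")
    stem = os.path.splitext(os.path.basename(path))[0]
    return StructureModel(structure_id=f"{stem}_{chain}", gene_label=stem, atoms=atoms)


_COORD_LIMIT = 9999.999


def _format_atom_name(name: str) -> str:
    # PDB columns 13-16: one/two-letter element names start in column 14
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_pdb(model: StructureModel, path: str | os.PathLike) -> None:
    """Write a model in fixed-column PDB format.

    Coordinates round-trip through :func:`parse_pdb` to 3 decimals.  Raises
    on empty models and on coordinates that overflow the %8.3f field.
    """
    if not model.atoms:
        raise ValueError("cannot write an empty model")
    lines = []
    for atom in model.atoms:
        x, y, z = atom.position
        if max(abs(x), abs(y), abs(z)) > _COORD_LIMIT or min(x, y, z) < -999.999:
            raise ValueError(
                f"coordinate {atom.position} of atom {atom.serial} overflows the PDB format"
            )
        record = "HETATM" if atom.is_hetero else "ATOM  "
        lines.append(
            f"{record}{atom.serial % 100000:5d} {_format_atom_name(atom.atom_name)}"
            f" {atom.residue_name:>3s} {atom.chain_id[:1]}{atom.residue_number:4d}"
            f"{atom.insertion_code[:1]}   {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}          {atom.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    pairing: list[tuple[int, int]] | None = None,
) -> tuple[StructureModel, float]:
    """Least-squares rigid-body superposition of ``mobile`` onto ``reference``.

    ``pairing`` lists (mobile_resnum, reference_resnum) pairs whose Cα atoms
    define the fit; by default residues with identical numbers are paired.
    Returns the transformed copy and the paired-Cα RMSD in Å.  The rotation is
    proper (no reflection).
    """
    if pairing is None:
        mob_res = {a.residue_number for a in mobile.ca_atoms()}
        ref_res = {a.residue_number for a in reference.ca_atoms()}
        pairing = [(r, r) for r in sorted(mob_res & ref_res)]

    mob_pts, ref_pts = [], []
    for mob_num, ref_num in pairing:
        ca_m = mobile.find_ca(mob_num)
        ca_r = reference.find_ca(ref_num)
        if ca_m is None or ca_r is None:
            raise ValueError(f"pairing ({mob_num}, {ref_num}): missing Cα atom")
        mob_pts.append(ca_m.position)
        ref_pts.append(ca_r.position)
    mob_pts = np.array(mob_pts)
    ref_pts = np.array(ref_pts)
    if len(mob_pts) < 3:
        raise ValueError("superposition requires at least 3 paired Cα atoms")

    mob_center = mob_pts.mean(axis=0)
    ref_center = ref_pts.mean(axis=0)
    mob_c = mob_pts - mob_center
    ref_c = ref_pts - ref_center
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise ValueError("paired Cα atoms are collinear; superposition is degenerate")

    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    rot_matrix = rot.as_matrix()
    translation = ref_center - rot_matrix @ mob_center
    transformed = mobile.transformed(rot_matrix, translation)
    fitted = (rot_matrix @ mob_pts.T).T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref_pts) ** 2, axis=1))))
    return transformed, rmsd


def define_membrane_plane(
    reference: StructureModel,
    anchor_residues: tuple[int, int, int],
    extracellular_probe: np.ndarray,
) -> MembranePlane:
    """Plane through three anchor Cα atoms, normal oriented toward the probe.

    For real receptor sets the anchors are residues 52, 163 and 214 of the
    rhodopsin reference (1F88 chain A), which lie at the bilayer midpoint;
    the probe is any point on the extracellular side.
    """
    anchors = []
    for resnum in anchor_residues:
        ca = reference.find_ca(resnum)
        if ca is None:
            raise ValueError(f"anchor residue {resnum} has no Cα atom")
        anchors.append(ca.position)
    anchors = np.array(anchors)

    normal = np.cross(anchors[1] - anchors[0], anchors[2] - anchors[0])
    norm = np.linalg.norm(normal)
    if norm < 1e-9:
        raise ValueError("anchor Cα atoms are collinear; plane undefined")
    normal = normal / norm
    offset = float(np.dot(normal, anchors[0]))
    probe_height = float(np.dot(normal, np.asarray(extracellular_probe, float)) - offset)
    if abs(probe_height) < 1e-9:
        raise ValueError("extracellular probe lies on the membrane plane")
    if probe_height < 0:
        normal = -normal
        offset = -offset
    return MembranePlane(anchor_points=anchors, unit_normal=normal, offset=offset)


def plane_from_point_normal(point: np.ndarray, normal: np.ndarray) -> MembranePlane:
    """Convenience constructor for synthetic frames (e.g. z = 0 midplane)."""
    point = np.asarray(point, float)
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    # build two in-plane anchors so the dataclass invariants hold
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    anchors = np.array([point, point + u, point + v])
    return MembranePlane(anchor_points=anchors, unit_normal=normal, offset=float(np.dot(normal, point)))
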