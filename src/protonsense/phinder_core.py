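"""Identify buried ionizable residues by computational geometry.

Asp, Glu, His, Lys and Arg side chains have pKa values far from neutrality in
water, but burial inside a protein shifts them into the physiological range;
buried ionizable residues are therefore strong candidates for pH-sensing
machinery.  The detection pipeline implemented here works in two phases:

1. the ionizable residues of a structure are triangulated (3-D Delaunay) into
   a geometric network, which is then minimized (long edges with shorter
   alternative paths removed) and trimmed of edges longer than 10 Å;
2. a closed triangulated surface is built from the Cα atoms (an alpha shape,
   so pockets and grooves are wrapped rather than bridged), each residue's
   signed depth relative to that surface is measured, and residues are
   classified as core (≤ -3.0 Å), margin, or exposed (> +1.05 Å).

The buried subnetwork keeps every core node plus any margin/exposed node that
shares a network edge with a core node.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import trimesh.triangles
from scipy.spatial import Delaunay, QhullError

from .structure_io import AtomRecord, StructureModel

IONIZABLE_RESIDUES = ("ASP", "GLU", "HIS", "LYS", "ARG")

#: atom bearing (or bracketing) the titratable charge of each residue type
CHARGE_GROUP_ATOMS = {
    "ASP": ("CG",),
    "GLU": ("CD",),
    "HIS": ("ND1", "NE2"),  # midpoint of the imidazole nitrogens
    "LYS": ("NZ",),
    "ARG": ("CZ",),
}

_BACKBONE = {"N", "CA", "C", "O", "OXT"}

BURIAL_CORE_MAX = -3.0  # depth ≤ -3.0 Å below the surface → core
BURIAL_EXPOSED_MIN = 1.05  # depth > +1.05 Å above the surface → exposed
DEFAULT_TRIM_CUTOFF = 10.0
DEFAULT_ALPHA_EDGE = 9.0

SiteKey = tuple[str, int, str]  # (chain, residue number, insertion code)


@dataclass
class IonizableSite:
    """One ionizable residue reduced to its charged-group reference point."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    reference_point: np.ndarray
    depth: float | None = None
    burial_class: str | None = None  # 'core' | 'margin' | 'exposed'

    def __post_init__(self):
        if self.residue_name not in IONIZABLE_RESIDUES:
            raise ValueError(f"{self.residue_name} is not an ionizable residue type")
        self.reference_point = np.asarray(self.reference_point, float)

    @property
    def key(self) -> SiteKey:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class ResidueNetwork:
    """Undirected geometric graph over ionizable sites with cached edge lengths."""

    sites: dict[SiteKey, IonizableSite] = field(default_factory=dict)
    edges: dict[tuple[SiteKey, SiteKey], float] = field(default_factory=dict)

    @staticmethod
    def edge_key(a: SiteKey, b: SiteKey) -> tuple[SiteKey, SiteKey]:
        if a == b:
            raise ValueError("self-edges are not allowed")
        return (a, b) if a < b else (b, a)

    def add_edge(self, a: SiteKey, b: SiteKey) -> None:
        key = self.edge_key(a, b)
        length = float(
            np.linalg.norm(self.sites[a].reference_point - self.sites[b].reference_point)
        )
        self.edges[key] = length

    def to_networkx(self, max_length: float | None = None) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.sites)
        for (a, b), length in self.edges.items():
            if max_length is None or length < max_length:
                g.add_edge(a, b, length=length)
        return g

    def copy(self) -> "ResidueNetwork":
        return ResidueNetwork(dict(self.sites), dict(self.edges))


@dataclass
class SurfaceMesh:
    """Closed, outward-oriented triangular surface over Cα positions."""

    vertices: np.ndarray  # (n, 3)
    facets: np.ndarray  # (m, 3) indices into vertices, oriented
    normals: np.ndarray  # (m, 3) outward unit normals
    neighbors: np.ndarray  # (m, 3) edge-adjacent facet indices (-1 if absent)
    alpha_edge: float

    @property
    def facet_triangles(self) -> np.ndarray:
        return self.vertices[self.facets]  # (m, 3, 3)

    def is_closed(self) -> bool:
        counts: dict[tuple[int, int], int] = {}
        for tri in self.facets:
            for e in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                counts[tuple(sorted(e))] = counts.get(tuple(sorted(e)), 0) + 1
        return all(c == 2 for c in counts.values())


def reference_point(residue_atoms: list[AtomRecord]) -> np.ndarray:
    """Charged-group reference point of one ionizable residue.

    Falls back to the side-chain centroid if the named charge-group atom is
    missing, then to Cβ; residues reduced to backbone N/C/O only are an error.
    """
    if not residue_atoms:
        raise ValueError("no atoms supplied")
    resname = residue_atoms[0].residue_name
    if resname not in IONIZABLE_RESIDUES:
        raise ValueError(f"{resname} is not an ionizable residue type")
    by_name = {a.atom_name: a for a in residue_atoms}

    wanted = CHARGE_GROUP_ATOMS[resname]
    if all(n in by_name for n in wanted):
        pts = np.array([by_name[n].position for n in wanted])
        return pts.mean(axis=0)

    side_chain = [a.position for a in residue_atoms if a.atom_name not in _BACKBONE]
    if side_chain:
        return np.mean(side_chain, axis=0)
    if "CB" in by_name:
        return by_name["CB"].position
    raise ValueError(f"{resname} {residue_atoms[0].residue_key}: no usable side-chain atoms")


def ionizable_sites(model: StructureModel) -> list[IonizableSite]:
    """All ionizable residues of a model as :class:`IonizableSite` objects."""
    sites = []
    for (chain, resnum, icode), atoms in model.residues().items():
        resname = atoms[0].residue_name
        if resname in IONIZABLE_RESIDUES and not atoms[0].is_hetero:
            sites.append(
                IonizableSite(chain, resnum, icode, resname, reference_point(atoms))
            )
    return sites


def _delaunay_edges(points: np.ndarray) -> set[tuple[int, int]] | None:
    """Edge set of the 3-D Delaunay tetrahedralization, or None if degenerate."""
    if len(points) < 5:
        return None
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-7) < 3:
        return None
    try:
        tri = Delaunay(points)
    except QhullError:
        return None
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for i, j in itertools.combinations(sorted(simplex), 2):
            edges.add((int(i), int(j)))
    return edges


def triangulate_sites(
    sites: list[IonizableSite], duplicate_jitter_seed: int = 0
) -> ResidueNetwork:
    """Build the ionizable-residue network by 3-D Delaunay triangulation.

    Fewer than five sites, or degenerate (coplanar/collinear) geometries where
    a tetrahedralization is undefined, fall back to the complete graph.
    Coincident reference points (within 1e-6 Å) are jittered by 1e-4 Å with a
    fixed seed so the triangulation is well defined and reproducible.
    """
    if len(sites) < 2:
        raise ValueError("triangulation requires at least 2 sites")

    sites = sorted(sites, key=lambda s: s.key)
    points = np.array([s.reference_point for s in sites])

    # resolve duplicate reference points deterministically
    rng = np.random.default_rng(duplicate_jitter_seed)
    for i, j in itertools.combinations(range(len(points)), 2):
        if np.linalg.norm(points[i] - points[j]) < 1e-6:
            points[j] = points[j] + rng.normal(scale=1e-4, size=3)
            sites[j] = replace(sites[j], reference_point=points[j])

    net = ResidueNetwork(sites={s.key: s for s in sites})
    edges = _delaunay_edges(points)
    if edges is None:
        edges = set(itertools.combinations(range(len(sites)), 2))
    for i, j in edges:
        net.add_edge(sites[i].key, sites[j].key)
    return net


def minimize_network(net: ResidueNetwork) -> ResidueNetwork:
    """Remove long edges that are redundant given strictly shorter paths.

    Repeatedly removes the longest remaining edge whose two endpoints stay
    connected through a path made entirely of strictly shorter edges;
    terminates when no edge is removable.  "Strictly shorter" means shorter
    by more than 1e-9 Å, so numerically equal lengths (e.g. an equilateral
    triangle) never justify a removal.  Ties are broken lexicographically by
    node key, making the result deterministic.
    """
    result = net.copy()
    while True:
        candidates = sorted(result.edges.items(), key=lambda kv: (-kv[1], kv[0]))
        removed = False
        for (a, b), length in candidates:
            shorter = nx.Graph()
            shorter.add_nodes_from(result.sites)
            for (u, v), l in result.edges.items():
                if l < length - 1e-9 and (u, v) != (a, b):
                    shorter.add_edge(u, v)
            if nx.has_path(shorter, a, b):
                del result.edges[(a, b)]
                removed = True
                break
        if not removed:
            return result


def trim_edges(net: ResidueNetwork, cutoff: float = DEFAULT_TRIM_CUTOFF) -> ResidueNetwork:
    """Drop every edge whose length exceeds the cutoff (10 Å by convention).

    An edge of length exactly equal to the cutoff does not exceed it and is
    kept.  Nodes are preserved; isolated nodes are allowed.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return ResidueNetwork(
        sites=dict(net.sites),
        edges={e: l for e, l in net.edges.items() if l <= cutoff},
    )


def _boundary_facets(points: np.ndarray, simplices: np.ndarray) -> tuple[np.ndarray, bool]:
    """Oriented boundary facets of a tetrahedral solid.

    Returns (facets, closed): facets of the largest edge-connected boundary
    component, each wound so its normal points away from the owning
    tetrahedron; closed is True when every edge of that component is shared by
    exactly two facets.
    """
    face_count: dict[tuple[int, int, int], list[tuple[np.ndarray, int]]] = {}
    for simplex in simplices:
        for omit in range(4):
            face = np.delete(simplex, omit)
            key = tuple(sorted(int(v) for v in face))
            face_count.setdefault(key, []).append((face, int(simplex[omit])))

    oriented = []
    for key, owners in face_count.items():
        if len(owners) != 1:
            continue
        face, opposite = owners[0]
        a, b, c = (points[v] for v in face)
        normal = np.cross(b - a, c - a)
        if np.dot(normal, points[opposite] - a) > 0:  # flip away from the tet interior
            face = face[[0, 2, 1]]
        oriented.append(np.asarray(face, int))
    if not oriented:
        return np.zeros((0, 3), int), False
    facets = np.array(oriented)

    # largest edge-connected component of the boundary
    edge_to_facets: dict[tuple[int, int], list[int]] = {}
    for fi, tri in enumerate(facets):
        for e in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            edge_to_facets.setdefault(tuple(sorted(map(int, e))), []).append(fi)
    g = nx.Graph()
    g.add_nodes_from(range(len(facets)))
    for flist in edge_to_facets.values():
        for i, j in itertools.combinations(flist, 2):
            g.add_edge(i, j)
    component = max(nx.connected_components(g), key=len)
    facets = facets[sorted(component)]

    counts: dict[tuple[int, int], int] = {}
    for tri in facets:
        for e in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = tuple(sorted(map(int, e)))
            counts[key] = counts.get(key, 0) + 1
    closed = all(c == 2 for c in counts.values())
    return facets, closed


def build_surface(model: StructureModel, alpha_edge: float = DEFAULT_ALPHA_EDGE) -> SurfaceMesh:
    """Alpha-shape surface over the Cα atoms of a structure.

    Tetrahedra of the Cα Delaunay tetrahedralization with any edge longer
    than ``alpha_edge`` are discarded; the boundary facets of the surviving
    solid form the mesh.  If discarding opens or fragments the solid,
    ``alpha_edge`` is raised in 0.5 Å steps until the largest boundary
    component is closed.  Facet normals point outward.
    """
    ca = model.ca_atoms()
    if len(ca) < 4:
        raise ValueError("surface construction requires at least 4 Cα atoms")
    points = np.array([a.position for a in ca])
    if np.linalg.matrix_rank(points - points.mean(axis=0), tol=1e-7) < 3:
        raise ValueError("Cα atoms are coplanar; no 3-D surface exists")

    tri = Delaunay(points)
    simplex_pts = points[tri.simplices]  # (t, 4, 3)
    pair_idx = list(itertools.combinations(range(4), 2))
    edge_lengths = np.stack(
        [np.linalg.norm(simplex_pts[:, i] - simplex_pts[:, j], axis=1) for i, j in pair_idx],
        axis=1,
    )
    max_edge = edge_lengths.max(axis=1)

    diameter = float(np.linalg.norm(points.max(axis=0) - points.min(axis=0))) + 1.0
    alpha = float(alpha_edge)
    while True:
        keep = tri.simplices[max_edge <= alpha]
        if len(keep):
            facets, closed = _boundary_facets(points, keep)
            if closed:
                break
        if alpha > diameter:
            raise ValueError("failed to build a closed surface at any alpha")
        alpha += 0.5

    triangles = points[facets]
    normals = np.cross(
        triangles[:, 1] - triangles[:, 0], triangles[:, 2] - triangles[:, 0]
    )
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValueError("degenerate facet in surface mesh")
    normals = normals / norms

    # edge-adjacency between facets
    edge_to_facets: dict[tuple[int, int], list[int]] = {}
    for fi, t in enumerate(facets):
        for e in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            edge_to_facets.setdefault(tuple(sorted(map(int, e))), []).append(fi)
    neighbors = -np.ones((len(facets), 3), dtype=int)
    slot = [0] * len(facets)
    for flist in edge_to_facets.values():
        if len(flist) == 2:
            i, j = flist
            neighbors[i, slot[i]] = j
            slot[i] += 1
            neighbors[j, slot[j]] = i
            slot[j] += 1

    return SurfaceMesh(
        vertices=points, facets=facets, normals=normals, neighbors=neighbors, alpha_edge=alpha
    )


def residue_depth(point: np.ndarray, mesh: SurfaceMesh) -> float:
    """Signed depth of a point relative to the surface mesh, in Å.

    The magnitude is the distance to the closest point on the mesh (the
    facet with the smallest point-to-facet distance; ties broken by facet
    index).  The side is decided by that facet together with its
    edge-adjacent neighbors: when the closest surface point falls on a
    shared edge or vertex, a single facet normal is ambiguous, so the
    outward normals of the closest facet and its neighbors vote.  Negative
    depths are inside (below) the surface; points on the surface have depth
    exactly 0.
    """
    point = np.asarray(point, float)
    triangles = mesh.facet_triangles
    tiled = np.repeat(point[None, :], len(triangles), axis=0)
    closest = trimesh.triangles.closest_point(triangles, tiled)
    distances = np.linalg.norm(closest - point, axis=1)
    best = int(np.argmin(distances))
    d = float(distances[best])
    if d < 1e-9:
        return 0.0

    offset = point - closest[best]
    facet_ids = [best] + [int(n) for n in mesh.neighbors[best] if n >= 0]
    side = float(np.sum([np.dot(mesh.normals[fi], offset) for fi in facet_ids]))
    return d if side > 0 else -d


def classify_burial(depth: float) -> str:
    """Burial class from signed depth: core / margin / exposed.

    Core: at least 3.0 Å below the surface (depth ≤ -3.0); exposed: more than
    1.05 Å above (depth > +1.05); margin: the band in between, inclusive of
    both boundary depths nearest it.
    """
    if not np.isfinite(depth):
        raise ValueError("depth must be finite")
    if depth <= BURIAL_CORE_MAX:
        return "core"
    if depth <= BURIAL_EXPOSED_MIN:
        return "margin"
    return "exposed"


def assign_depths(net: ResidueNetwork, mesh: SurfaceMesh) -> ResidueNetwork:
    """Return a copy of the network with depth and burial class filled in."""
    out = ResidueNetwork(edges=dict(net.edges))
    for key, site in net.sites.items():
        d = residue_depth(site.reference_point, mesh)
        out.sites[key] = replace(site, depth=d, burial_class=classify_burial(d))
    return out


def extract_buried_network(net: ResidueNetwork) -> ResidueNetwork:
    """Subnetwork of buried residues.

    Keeps every core node, plus any margin or exposed node that shares a
    network edge with a core node; edges are those of the input network
    between kept nodes.
    """
    for key, site in net.sites.items():
        if site.burial_class is None:
            raise ValueError(f"site {key} has no burial class assigned")
    core = {k for k, s in net.sites.items() if s.burial_class == "core"}
    kept = set(core)
    for (a, b) in net.edges:
        if a in core:
            kept.add(b)
        if b in core:
            kept.add(a)
    return ResidueNetwork(
        sites={k: net.sites[k] for k in sorted(kept)},
        edges={(a, b): l for (a, b), l in net.edges.items() if a in kept and b in kept},
    )


def run_phinder(
    model: StructureModel,
    trim_cutoff: float = DEFAULT_TRIM_CUTOFF,
    alpha_edge: float = DEFAULT_ALPHA_EDGE,
) -> tuple[ResidueNetwork, ResidueNetwork, SurfaceMesh]:
    """Full buried-ionizable-residue calculation for one structure.

    Returns (classified full network, buried subnetwork, surface mesh).
    """
    sites = ionizable_sites(model)
    mesh = build_surface(model, alpha_edge)
    if len(sites) < 2:
        # degenerate structures: classify what is there, no edges to build
        net = ResidueNetwork(sites={s.key: s for s in sites})
    else:
        net = triangulate_sites(sites)
        net = minimize_network(net)
        net = trim_edges(net, trim_cutoff)
    net = assign_depths(net, mesh)
    return net, extract_buried_network(net), mesh


def write_mesh_off(mesh: SurfaceMesh, path) -> None:
    """Write the surface mesh in OFF format."""
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(mesh.vertices)} {len(mesh.facets)} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.4f} {v[1]:.4f} {v[2]:.4f}\n")
        for f in mesh.facets:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
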