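"""Consensus network analysis (CNA) across superposed structures.

When many structures of related receptors are superposed into one frame, a
residue (or bound ion) that occupies the same spatial position in structure
after structure shows up as a tight cloud of points.  CNA finds those clouds:
pooled points are triangulated, edges longer than a cutoff (1.5 Å for buried
network nodes, 2.0 Å for Na+ ions) are removed, and connected components with
at least ``min_size`` members are reported as consensus clusters.  Because a
gene represented by many structures would inflate a cluster by itself,
clustering is run in two rounds: round one locates clusters of any size,
redundant same-gene contributions are reduced to the member nearest the
cluster centroid, and round two reclusters the survivors with the real
minimum size.

The same module counts extracellular histidines (eHis): His residues whose
Cα lies above the membrane midplane, reported per structure and, across
structures of one gene, as the per-gene maximum.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import pdist, squareform

from .phinder_core import ResidueNetwork
from .structure_io import MembranePlane, StructureModel

DEFAULT_NODE_CUTOFF = 1.5
DEFAULT_ION_CUTOFF = 2.0
DEFAULT_MIN_CLUSTER_SIZE = 5


@dataclass(frozen=True, eq=False)
class LabeledPoint:
    """One pooled point in the common reference frame.

    Instances compare by identity (positions are arrays), which is what
    cluster-membership bookkeeping needs.
    """

    position: np.ndarray
    structure_id: str
    gene_label: str
    payload: str = ""  # residue identity or ion element

    def __post_init__(self):
        pos = np.asarray(self.position, float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        if not self.gene_label:
            raise ValueError("gene_label must be non-empty")
        object.__setattr__(self, "position", pos)


@dataclass
class ConsensusCluster:
    """A spatially conserved cluster of pooled points."""

    members: list[LabeledPoint]
    centroid: np.ndarray = field(init=False)

    def __post_init__(self):
        self.centroid = np.mean([m.position for m in self.members], axis=0)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def genes(self) -> set[str]:
        return {m.gene_label for m in self.members}


def _connected_components(points: np.ndarray, cutoff: float) -> list[list[int]]:
    """Components of the trimmed point graph.

    Connectivity comes from the Delaunay edge graph trimmed at ``cutoff``,
    cross-checked against the brute-force cutoff graph (all pairs within
    ``cutoff``); when the two partitions disagree the brute-force graph wins,
    since the Delaunay graph can omit short edges between points it does not
    connect.
    """
    n = len(points)
    if n == 1:
        return [[0]]
    dist = squareform(pdist(points))

    brute = nx.Graph()
    brute.add_nodes_from(range(n))
    for i, j in zip(*np.nonzero(np.triu(dist <= cutoff, k=1))):
        brute.add_edge(int(i), int(j))
    brute_parts = sorted(sorted(c) for c in nx.connected_components(brute))

    delaunay_edges: set[tuple[int, int]] | None = None
    if n >= 5 and np.linalg.matrix_rank(points - points.mean(axis=0), tol=1e-7) == 3:
        try:
            tri = Delaunay(points)
            delaunay_edges = set()
            for simplex in tri.simplices:
                for i, j in itertools.combinations(sorted(map(int, simplex)), 2):
                    delaunay_edges.add((i, j))
        except QhullError:
            delaunay_edges = None

    if delaunay_edges is not None:
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i, j in delaunay_edges:
            if dist[i, j] <= cutoff:
                g.add_edge(i, j)
        parts = sorted(sorted(c) for c in nx.connected_components(g))
        if parts == brute_parts:
            return parts
    return brute_parts


def cna_cluster(
    points: list[LabeledPoint],
    cutoff: float = DEFAULT_NODE_CUTOFF,
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE,
) -> list[ConsensusCluster]:
    """One round of consensus clustering.

    Pools the points, triangulates (complete graph for <5 or degenerate
    inputs), trims edges longer than ``cutoff`` and returns connected
    components with at least ``min_size`` members, sorted by decreasing size
    then lexicographic centroid.
    """
    if not points:
        raise ValueError("no points to cluster")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if min_size < 1:
        raise ValueError("min_size must be at least 1")

    coords = np.array([p.position for p in points])
    components = _connected_components(coords, cutoff)
    clusters = [
        ConsensusCluster([points[i] for i in comp])
        for comp in components
        if len(comp) >= min_size
    ]
    clusters.sort(key=lambda c: (-c.size, tuple(np.round(c.centroid, 9))))
    return clusters


def deduplicate_by_gene(cluster: ConsensusCluster) -> list[LabeledPoint]:
    """At most one member per gene: the one nearest the cluster centroid.

    Distance ties break lexicographically by structure_id.
    """
    best: dict[str, LabeledPoint] = {}
    for member in cluster.members:
        d = float(np.linalg.norm(member.position - cluster.centroid))
        incumbent = best.get(member.gene_label)
        if incumbent is None:
            best[member.gene_label] = member
        else:
            d_inc = float(np.linalg.norm(incumbent.position - cluster.centroid))
            if (d, member.structure_id) < (d_inc, incumbent.structure_id):
                best[member.gene_label] = member
    return [best[g] for g in sorted(best)]


def two_round_cna(
    points: list[LabeledPoint],
    cutoff: float = DEFAULT_NODE_CUTOFF,
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE,
) -> list[ConsensusCluster]:
    """Two-round CNA with per-gene redundancy removal between rounds.

    Round one clusters with ``min_size`` 1 so that every co-located group is
    seen; each round-one cluster is reduced to one member per gene; round two
    reclusters the survivors at the requested ``cutoff`` and ``min_size``.
    """
    round1 = cna_cluster(points, cutoff=cutoff, min_size=1)
    survivors: list[LabeledPoint] = []
    for cluster in round1:
        survivors.extend(deduplicate_by_gene(cluster))
    return cna_cluster(survivors, cutoff=cutoff, min_size=min_size)


def cluster_ions(
    ion_points: list[LabeledPoint],
    cutoff: float = DEFAULT_ION_CUTOFF,
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE,
) -> list[ConsensusCluster]:
    """Two-round CNA over pooled Na+ positions (2.0 Å cutoff, min size 5)."""
    if not ion_points:
        return []
    return two_round_cna(ion_points, cutoff=cutoff, min_size=min_size)


def pool_network_nodes(
    networks: list[tuple[StructureModel, ResidueNetwork]]
) -> list[LabeledPoint]:
    """Pool buried-network node positions from many superposed structures."""
    points = []
    for model, net in networks:
        for site in net.sites.values():
            points.append(
                LabeledPoint(
                    position=site.reference_point,
                    structure_id=model.structure_id,
                    gene_label=model.gene_label,
                    payload=f"{site.residue_name}{site.residue_number}",
                )
            )
    return points


def pool_ions(models: list[StructureModel], element: str = "NA") -> list[LabeledPoint]:
    """Pool HETATM ion positions (default Na+) from superposed structures."""
    points = []
    for model in models:
        for pos in model.hetero_positions(element):
            points.append(
                LabeledPoint(
                    position=pos,
                    structure_id=model.structure_id,
                    gene_label=model.gene_label,
                    payload=element,
                )
            )
    return points


class EHisCount(int):
    """Integer eHis count carrying a diagnostic of His residues skipped for
    lacking a Cα atom."""

    skipped_missing_ca: int

    def __new__(cls, count: int, skipped_missing_ca: int = 0):
        obj = super().__new__(cls, count)
        obj.skipped_missing_ca = skipped_missing_ca
        return obj


def count_ehis(model: StructureModel, plane: MembranePlane) -> EHisCount:
    """Number of extracellular His residues of a superposed structure.

    A His is extracellular when its Cα lies strictly above the membrane
    midplane; a His exactly on the plane (|height| ≤ 1e-9) is not counted.
    His residues lacking a Cα are skipped with a warning and tallied in the
    result's ``skipped_missing_ca`` field.
    """
    count = 0
    skipped = 0
    for key, atoms in model.residues().items():
        if atoms[0].residue_name != "HIS" or atoms[0].is_hetero:
            continue
        ca = next((a for a in atoms if a.atom_name == "CA"), None)
        if ca is None:
            warnings.warn(f"His {key} has no Cα atom; skipped from eHis count")
            skipped += 1
            continue
        if plane.signed_height(ca.position) > 1e-9:
            count += 1
    return EHisCount(count, skipped)


def gene_max_ehis(counts: dict[str, tuple[str, int]]) -> dict[str, int]:
    """Per-gene maximum eHis count over that gene's structures.

    ``counts`` maps structure_id -> (gene_label, count); genes represented by
    several structures report the structure with the greatest count.
    """
    if not counts:
        raise ValueError("no eHis counts supplied")
    result: dict[str, int] = {}
    for _sid, (gene, count) in counts.items():
        result[gene] = max(result.get(gene, int(count)), int(count))
    return result
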