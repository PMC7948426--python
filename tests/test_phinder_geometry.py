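"""Ionizable-residue network construction: triangulation, minimization, trimming.

The brute-force oracles here are deliberately independent of the library
implementation: circumspheres are solved directly from 4-point subsets, and
the minimization rule is re-applied by exhaustive scanning.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protonsense.phinder_core import (
    IonizableSite,
    ResidueNetwork,
    extract_buried_network,
    classify_burial,
    minimize_network,
    reference_point,
    triangulate_sites,
    trim_edges,
)
from protonsense.structure_io import AtomRecord


def make_sites(points, resname="ASP"):
    return [
        IonizableSite("A", i + 1, " ", resname, np.asarray(p, float))
        for i, p in enumerate(points)
    ]


def atom(name, pos, resname="ASP", resnum=1):
    return AtomRecord(1, name, resname, "A", resnum, " ", np.asarray(pos, float), "C", False)


def circumsphere(points):
    """Center and radius of the sphere through 4 points (None if coplanar)."""
    a, b, c, d = (np.asarray(p, float) for p in points)
    mat = np.array([b - a, c - a, d - a])
    rhs = 0.5 * np.array(
        [np.dot(b, b) - np.dot(a, a), np.dot(c, c) - np.dot(a, a), np.dot(d, d) - np.dot(a, a)]
    )
    if abs(np.linalg.det(mat)) < 1e-9:
        return None, None
    center = np.linalg.solve(mat, rhs)
    return center, float(np.linalg.norm(center - a))


class TestReferencePoint:
    def test_asp_uses_cg(self):
        atoms = [atom("CA", (0, 0, 0)), atom("CG", (1, 2, 3))]
        np.testing.assert_allclose(reference_point(atoms), [1, 2, 3])

    def test_his_midpoint_of_imidazole_nitrogens(self):
        atoms = [
            atom("ND1", (0, 0, 0), "HIS"),
            atom("NE2", (2, 0, 0), "HIS"),
        ]
        np.testing.assert_allclose(reference_point(atoms), [1, 0, 0])

    def test_lys_missing_nz_falls_back_to_side_chain_centroid(self):
        side = {"CB": (0, 0, 0), "CG": (1, 0, 0), "CD": (2, 0, 0), "CE": (3, 0, 0)}
        atoms = [atom("CA", (9, 9, 9), "LYS")] + [
            atom(n, p, "LYS") for n, p in side.items()
        ]
        np.testing.assert_allclose(reference_point(atoms), [1.5, 0, 0])

    def test_cb_only_fallback(self):
        atoms = [atom("CA", (0, 0, 0), "ARG"), atom("CB", (1, 1, 1), "ARG")]
        np.testing.assert_allclose(reference_point(atoms), [1, 1, 1])

    def test_backbone_only_raises(self):
        atoms = [atom("N", (0, 0, 0)), atom("CA", (1, 0, 0)), atom("C", (2, 0, 0))]
        with pytest.raises(ValueError, match="no usable"):
            reference_point(atoms)

    def test_non_ionizable_raises(self):
        with pytest.raises(ValueError, match="not an ionizable"):
            reference_point([atom("CA", (0, 0, 0), "ALA")])


class TestTriangulateSites:
    def test_two_points_single_edge(self):
        net = triangulate_sites(make_sites([(0, 0, 0), (3, 0, 0)]))
        assert len(net.edges) == 1
        assert list(net.edges.values()) == [pytest.approx(3.0)]

    def test_four_points_complete_graph(self):
        net = triangulate_sites(
            make_sites([(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)])
        )
        assert len(net.edges) == 6

    def test_coplanar_points_complete_graph(self):
        pts = [(x, y, 0.0) for x in range(3) for y in range(2)]
        net = triangulate_sites(make_sites(pts))
        assert len(net.edges) == 6 * 5 // 2

    def test_single_site_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            triangulate_sites(make_sites([(0, 0, 0)]))

    def test_cached_lengths_match_geometry(self):
        rng = np.random.default_rng(3)
        net = triangulate_sites(make_sites(rng.uniform(0, 20, (15, 3))))
        for (a, b), length in net.edges.items():
            d = np.linalg.norm(net.sites[a].reference_point - net.sites[b].reference_point)
            assert length == pytest.approx(d, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_delaunay_edges_have_empty_circumsphere_witness(self, seed):
        """Every network edge belongs to a 4-subset whose circumsphere is
        empty of all other points (brute force over all 4-subsets)."""
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 20, (20, 3))
        net = triangulate_sites(make_sites(pts))
        index = {s.key: i for i, s in enumerate(make_sites(pts))}
        for a, b in net.edges:
            ia, ib = index[a], index[b]
            found = False
            others = [i for i in range(len(pts)) if i not in (ia, ib)]
            for ic, id_ in itertools.combinations(others, 2):
                center, radius = circumsphere(pts[[ia, ib, ic, id_]])
                if center is None:
                    continue
                dists = np.linalg.norm(pts - center, axis=1)
                inside = dists < radius - 1e-7
                inside[[ia, ib, ic, id_]] = False
                if not inside.any():
                    found = True
                    break
            assert found, f"edge {a}-{b} has no empty-circumsphere witness"

    def test_duplicate_points_jittered_deterministically(self):
        pts = [(0, 0, 0), (0, 0, 0), (5, 0, 0), (0, 5, 0), (0, 0, 5)]
        n1 = triangulate_sites(make_sites(pts))
        n2 = triangulate_sites(make_sites(pts))
        assert n1.edges == n2.edges
        for site in n1.sites.values():
            assert np.all(np.isfinite(site.reference_point))


def brute_force_minimize(net: ResidueNetwork) -> ResidueNetwork:
    """Independent re-implementation of the minimization rule: exhaustively
    scan for the longest edge bypassed by a strictly-shorter path."""
    sites = dict(net.sites)
    edges = dict(net.edges)

    def has_shorter_path(a, b, limit):
        # Dijkstra-free BFS over the subgraph of edges strictly shorter than limit
        frontier, seen = {a}, {a}
        while frontier:
            nxt = set()
            for (u, v), l in edges.items():
                if l >= limit - 1e-9:
                    continue
                for x, y in ((u, v), (v, u)):
                    if x in frontier and y not in seen:
                        nxt.add(y)
                        seen.add(y)
            if b in seen:
                return True
            frontier = nxt
        return False

    while True:
        for (a, b), length in sorted(edges.items(), key=lambda kv: (-kv[1], kv[0])):
            if has_shorter_path(a, b, length):
                del edges[(a, b)]
                break
        else:
            return ResidueNetwork(sites, edges)


class TestMinimizeNetwork:
    def _net(self, points):
        return triangulate_sites(make_sites(points))

    def test_345_triangle_drops_hypotenuse(self):
        net = self._net([(0, 0, 0), (3, 0, 0), (0, 4, 0)])
        out = minimize_network(net)
        assert len(out.edges) == 2
        assert max(out.edges.values()) == pytest.approx(4.0)

    def test_equilateral_triangle_unchanged(self):
        net = self._net([(0, 0, 0), (2, 0, 0), (1, np.sqrt(3), 0)])
        out = minimize_network(net)
        assert len(out.edges) == 3

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_rule(self, seed):
        rng = np.random.default_rng(seed)
        net = self._net(rng.uniform(0, 15, (10, 3)))
        assert minimize_network(net).edges == brute_force_minimize(net).edges

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_never_disconnects(self, seed):
        rng = np.random.default_rng(seed)
        net = self._net(rng.uniform(0, 15, (12, 3)))
        assert len(list(_components(net))) == len(list(_components(minimize_network(net))))


def _components(net):
    import networkx as nx

    return nx.connected_components(net.to_networkx())


class TestTrimEdges:
    def test_boundary_length_kept(self):
        sites = make_sites([(0, 0, 0), (9.9, 0, 0), (0, 10.0, 0), (0, 0, 10.1)])
        net = ResidueNetwork(sites={s.key: s for s in sites})
        keys = [s.key for s in sites]
        for other in keys[1:]:
            net.add_edge(keys[0], other)
        out = trim_edges(net, 10.0)
        assert sorted(np.round(list(out.edges.values()), 6)) == [9.9, 10.0]
        assert set(out.sites) == set(net.sites)  # isolated nodes preserved

    def test_empty_network_passthrough(self):
        net = ResidueNetwork()
        assert trim_edges(net, 10.0).edges == {}

    def test_nonpositive_cutoff_raises(self):
        with pytest.raises(ValueError):
            trim_edges(ResidueNetwork(), 0.0)

    @given(st.integers(min_value=0, max_value=10_000), st.floats(min_value=2.0, max_value=25.0))
    @settings(max_examples=40, deadline=None)
    def test_equals_brute_force_filter(self, seed, cutoff):
        """Trimming is exactly the all-pairs length filter on the edge set."""
        rng = np.random.default_rng(seed)
        net = triangulate_sites(make_sites(rng.uniform(0, 20, (12, 3))))
        out = trim_edges(net, cutoff)
        expected = {e for e, l in net.edges.items() if l <= cutoff}
        assert set(out.edges) == expected


class TestClassifyAndExtract:
    @pytest.mark.parametrize(
        "depth,expected",
        [
            (-3.0, "core"),
            (-2.99, "margin"),
            (0.0, "margin"),
            (1.05, "margin"),
            (1.06, "exposed"),
            (-50.0, "core"),
            (50.0, "exposed"),
        ],
    )
    def test_threshold_boundaries(self, depth, expected):
        assert classify_burial(depth) == expected

    def test_nonfinite_depth_raises(self):
        with pytest.raises(ValueError):
            classify_burial(float("nan"))

    @given(st.floats(-20, 20), st.floats(-20, 20))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_depth(self, d1, d2):
        order = {"core": 0, "margin": 1, "exposed": 2}
        lo, hi = sorted([d1, d2])
        assert order[classify_burial(lo)] <= order[classify_burial(hi)]

    def _classified_net(self, classes, edges):
        sites = make_sites([(i, 0, 0) for i in range(len(classes))])
        net = ResidueNetwork(sites={s.key: s for s in sites})
        keys = [s.key for s in sites]
        for i, cls in enumerate(classes):
            net.sites[keys[i]].burial_class = cls
            net.sites[keys[i]].depth = {"core": -5.0, "margin": 0.0, "exposed": 3.0}[cls]
        for i, j in edges:
            net.add_edge(keys[i], keys[j])
        return net, keys

    def test_all_exposed_gives_empty_network(self):
        net, _ = self._classified_net(["exposed"] * 4, [(0, 1), (1, 2), (2, 3)])
        out = extract_buried_network(net)
        assert not out.sites and not out.edges

    def test_core_adjacency_rule(self):
        """core-margin-exposed chain keeps core, its margin neighbor, and
        only the edge between them."""
        net, keys = self._classified_net(
            ["core", "margin", "exposed"], [(0, 1), (1, 2)]
        )
        out = extract_buried_network(net)
        assert set(out.sites) == {keys[0], keys[1]}
        assert set(out.edges) == {ResidueNetwork.edge_key(keys[0], keys[1])}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_set_construction(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        classes = rng.choice(["core", "margin", "exposed"], size=n).tolist()
        edges = [
            (i, j)
            for i, j in itertools.combinations(range(n), 2)
            if rng.random() < 0.25
        ]
        net, keys = self._classified_net(classes, edges)
        out = extract_buried_network(net)
        core = {keys[i] for i in range(n) if classes[i] == "core"}
        expected = set(core)
        for i, j in edges:
            if keys[i] in core:
                expected.add(keys[j])
            if keys[j] in core:
                expected.add(keys[i])
        assert set(out.sites) == expected

    def test_unclassified_node_raises(self):
        sites = make_sites([(0, 0, 0), (1, 0, 0)])
        net = ResidueNetwork(sites={s.key: s for s in sites})
        with pytest.raises(ValueError, match="burial class"):
            extract_buried_network(net)
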