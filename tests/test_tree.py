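"""Skeleton trees: admissible edges, constrained MST, paths, tabu search."""

import itertools

import networkx as nx
import numpy as np
import pytest

from emtrace import (Edge, SkeletonTree, admissible_edges, build_mst,
                     k_longest_paths, tabu_refine, tree_score)
from tests.conftest import fully_adjacent, make_ldp


def random_ldps(rng, n, box=8.0, adjacency="full"):
    pts = rng.uniform(0, box, size=(n, 3))
    theta = rng.uniform(0.1, 1.0, size=n)
    ldps = [make_ldp(i, pts[i], theta=float(theta[i])) for i in range(n)]
    if adjacency == "full":
        fully_adjacent(ldps)
    else:  # random sparse symmetric adjacency, kept connected
        for i in range(1, n):
            j = int(rng.integers(0, i))
            ldps[i].adjacent_ids.add(j)
            ldps[j].adjacent_ids.add(i)
        for _ in range(n):
            a, b = rng.integers(0, n, size=2)
            if a != b:
                ldps[a].adjacent_ids.add(int(b))
                ldps[b].adjacent_ids.add(int(a))
    return ldps


def nx_graph(edges):
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.a, e.b, weight=e.w, cost=e.w_cost, edge=e)
    return g


def oracle_longest_paths(tree, n_paths):
    """Edge-disjoint longest paths by explicit all-pairs enumeration."""
    g = nx_graph(tree.edges)
    out = []
    for _ in range(n_paths):
        best = None
        for comp in nx.connected_components(g):
            nodes = sorted(comp)
            for u, v in itertools.combinations(nodes, 2):
                path = nx.shortest_path(g, u, v)
                cost = sum(g[a][b]["cost"] for a, b in zip(path, path[1:]))
                if best is None or cost > best[0] + 1e-12:
                    best = (cost, path)
        if best is None or not g.edges:
            break
        cost, path = best
        if cost <= 0 and len(path) < 2:
            break
        out.append((path, cost))
        for a, b in zip(path, path[1:]):
            g.remove_edge(a, b)
        g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])
        if not g.edges:
            break
    return out


class TestAdmissibleEdges:
    def test_two_ldps_single_edge(self):
        ldps = fully_adjacent([make_ldp(0, (0, 0, 0)), make_ldp(1, (1, 0, 0))])
        edges = admissible_edges(ldps, r_local=5.0)
        assert [(e.a, e.b) for e in edges] == [(0, 1)]

    def test_collinear_chord_dropped(self, line_ldps):
        # local MSTs on {0,1,2} keep 0-1 and 1-2 and drop the 2 A chord 0-2
        edges = admissible_edges(line_ldps, r_local=10.0)
        assert {(e.a, e.b) for e in edges} == {(0, 1), (1, 2)}

    def test_every_admissible_edge_in_some_local_mst(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            ldps = random_ldps(rng, 10, adjacency="sparse")
            r_local = 6.0
            edges = admissible_edges(ldps, r_local)
            by_id = {l.id: l for l in ldps}
            # brute-force recheck: rebuild each ball's MST with networkx
            found = set()
            for center in ldps:
                ball = {l.id for l in ldps
                        if np.linalg.norm(l.position - center.position) <= r_local}
                g = nx.Graph()
                g.add_nodes_from(ball)
                for l in ldps:
                    if l.id not in ball:
                        continue
                    for o in l.adjacent_ids:
                        if o in ball:
                            w = float(np.linalg.norm(l.position - by_id[o].position))
                            g.add_edge(l.id, o, weight=w)
                for a, b in nx.minimum_spanning_edges(g, data=False):
                    found.add((min(a, b), max(a, b)))
            got = {(e.a, e.b) for e in edges}
            # every returned edge connects adjacent LDPs and lies in a ball MST
            for e in edges:
                assert e.b in by_id[e.a].adjacent_ids
            # MST tie-breaking may differ between implementations only when
            # equal-weight edges exist; random reals make ties negligible
            assert got == found


class TestBuildMST:
    def test_two_node_tree(self):
        ldps = fully_adjacent([make_ldp(0, (0, 0, 0)), make_ldp(1, (0, 2, 0))])
        tree = build_mst(ldps, admissible_edges(ldps, 5.0))
        assert len(tree.edges) == 1
        assert tree.total_length == pytest.approx(2.0)

    def test_unit_square_against_enumeration(self):
        corners = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)]
        ldps = fully_adjacent([make_ldp(i, c) for i, c in enumerate(corners)])
        edges = [Edge(a, b, float(np.linalg.norm(np.array(corners[a]) -
                                                 np.array(corners[b]))), 1.0)
                 for a, b in itertools.combinations(range(4), 2)]
        tree = build_mst(ldps, edges)
        # oracle: enumerate all 16 labeled spanning trees of K4
        g = nx_graph(edges)
        best = min(sum(d["weight"] for _, _, d in t.edges(data=True))
                   for t in nx.SpanningTreeIterator(g))
        assert tree.total_length == pytest.approx(best)
        assert tree.total_length == pytest.approx(3.0)

    def test_restricted_edge_set_respected(self):
        corners = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)]
        ldps = fully_adjacent([make_ldp(i, c) for i, c in enumerate(corners)])
        # exclude the 0-1 edge: MST must be built from the rest only
        edges = [Edge(a, b, float(np.linalg.norm(np.array(corners[a]) -
                                                 np.array(corners[b]))), 1.0)
                 for a, b in itertools.combinations(range(4), 2)
                 if (a, b) != (0, 1)]
        tree = build_mst(ldps, edges)
        assert (0, 1) not in tree.edge_keys()
        g = nx_graph(edges)
        best = min(sum(d["weight"] for _, _, d in t.edges(data=True))
                   for t in nx.SpanningTreeIterator(g))
        assert tree.total_length == pytest.approx(best)

    def test_matches_networkx_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(3, 9))
            ldps = random_ldps(rng, n, adjacency="sparse")
            edges = admissible_edges(ldps, r_local=8.0)
            tree = build_mst(ldps, edges)
            g = nx_graph(edges)
            comp = max(nx.connected_components(g), key=len)
            sub = g.subgraph(comp)
            expect = sum(d["weight"] for _, _, d in
                         nx.minimum_spanning_tree(sub).edges(data=True))
            assert tree.total_length == pytest.approx(expect, abs=1e-9)

    def test_spanning_tree_invariants(self):
        rng = np.random.default_rng(3)
        ldps = random_ldps(rng, 12, adjacency="sparse")
        edges = admissible_edges(ldps, r_local=8.0)
        tree = build_mst(ldps, edges)
        assert len(tree.edges) == len(tree.vertices) - 1
        admissible_keys = {e.key for e in edges}
        assert tree.edge_keys() <= admissible_keys


class TestLongestPaths:
    def test_simple_path_graph(self):
        edges = [Edge(0, 1, 1.0, 1.0), Edge(1, 2, 1.0, 2.0)]
        tree = SkeletonTree([0, 1, 2], edges)
        paths = k_longest_paths(tree, 5)
        assert len(paths) == 1
        assert paths[0][1] == pytest.approx(3.0)
        assert paths[0][0] in ([0, 1, 2], [2, 1, 0])

    def test_star_decomposition(self):
        edges = [Edge(0, 1, 1.0, 3.0), Edge(0, 2, 1.0, 2.0), Edge(0, 3, 1.0, 1.0)]
        tree = SkeletonTree([0, 1, 2, 3], edges)
        paths = k_longest_paths(tree, 5)
        assert [round(t, 6) for _, t, _ in paths] == [5.0, 1.0]
        assert tree_score(tree, 100) == pytest.approx(26.0)

    def test_single_edge_score(self):
        tree = SkeletonTree([0, 1], [Edge(0, 1, 1.0, 2.0)])
        assert tree_score(tree) == pytest.approx(4.0)

    def test_random_trees_match_all_pairs_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            g = nx.random_labeled_tree(n, seed=int(rng.integers(1 << 30)))
            edges = [Edge(a, b, 1.0, float(rng.uniform(0.1, 2.0)))
                     for a, b in g.edges]
            tree = SkeletonTree(list(range(n)), edges)
            got = k_longest_paths(tree, 100)
            expect = oracle_longest_paths(tree, 100)
            assert len(got) == len(expect)
            for (gv, gt, ge), (ev, et) in zip(got, expect):
                assert gt == pytest.approx(et, abs=1e-9)
            # edge-disjointness
            seen = set()
            for _, _, es in got:
                keys = {e.key for e in es}
                assert not (keys & seen)
                seen |= keys

    def test_score_monotone_in_n_paths(self):
        rng = np.random.default_rng(2)
        g = nx.random_labeled_tree(10, seed=4)
        edges = [Edge(a, b, 1.0, float(rng.uniform(0.1, 2.0))) for a, b in g.edges]
        tree = SkeletonTree(list(range(10)), edges)
        scores = [tree_score(tree, k) for k in (1, 2, 4, 8, 100)]
        assert scores == sorted(scores)
        assert scores[0] == pytest.approx(k_longest_paths(tree, 1)[0][1] ** 2)


def _grid_instance():
    """Small instance whose MST's longest path is improvable by one swap."""
    # 6 nodes: a zig-zag chain plus a shortcut edge slightly longer than the
    # chain edges; dense costs favor rerouting through the shortcut
    pos = {0: (0, 0, 0), 1: (1.0, 0, 0), 2: (2.0, 0, 0), 3: (3.0, 0, 0),
           4: (1.5, 1.2, 0), 5: (4.0, 0, 0)}
    theta = {0: 1.0, 1: 1.0, 2: 0.05, 3: 1.0, 4: 1.0, 5: 1.0}
    ldps = [make_ldp(i, pos[i], theta=theta[i]) for i in range(6)]
    fully_adjacent(ldps)
    edges = []
    for a, b in itertools.combinations(range(6), 2):
        w = float(np.linalg.norm(np.array(pos[a]) - np.array(pos[b])))
        if w <= 2.0:
            edges.append(Edge(a, b, w, w * min(theta[a], theta[b])))
    return ldps, edges


class TestTabuRefine:
    def test_no_deletable_edges_is_identity(self):
        edges = [Edge(0, 1, 0.4, 0.4), Edge(1, 2, 0.3, 0.3)]
        tree = SkeletonTree([0, 1, 2], edges)
        out = tabu_refine(tree, edges, d_keep=0.5, n_iter=5, seed=1)
        assert out.edge_keys() == tree.edge_keys()

    def test_deterministic_given_seed(self):
        ldps, edges = _grid_instance()
        mst = build_mst(ldps, edges)
        a = tabu_refine(mst, edges, d_keep=0.5, n_iter=20, seed=9)
        b = tabu_refine(mst, edges, d_keep=0.5, n_iter=20, seed=9)
        assert a.edge_keys() == b.edge_keys()

    def test_score_never_decreases_and_reaches_optimum(self):
        ldps, edges = _grid_instance()
        mst = build_mst(ldps, edges)
        s0 = tree_score(mst)
        refined = tabu_refine(mst, edges, d_keep=0.5, n_iter=50, seed=3)
        s1 = tree_score(refined)
        assert s1 >= s0 - 1e-9
        # exhaustive optimum over admissible spanning trees within the
        # length budget
        g = nx_graph(edges)
        best = None
        limit = 1.01 * mst.total_length + 1e-9
        for t in nx.SpanningTreeIterator(g):
            es = [g[a][b]["edge"] for a, b in t.edges]
            if sum(e.w for e in es) > limit:
                continue
            st = SkeletonTree(list(g.nodes), es)
            s = tree_score(st)
            if best is None or s > best:
                best = s
        assert s1 == pytest.approx(best, rel=1e-9)

    def test_length_budget_respected(self):
        ldps, edges = _grid_instance()
        mst = build_mst(ldps, edges)
        refined = tabu_refine(mst, edges, d_keep=0.5, n_iter=50, seed=3)
        assert refined.total_length <= 1.01 * mst.total_length + 1e-9
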