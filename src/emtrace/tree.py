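"""Skeleton trees over LDPs: constrained MST, path scoring, tabu refinement.

The LDP cloud is connected into a spanning tree that minimizes total
Euclidean edge length, restricted to an admissible edge set: LDP pairs that
are grid-adjacent AND appear in at least one local MST (the MST of the LDPs
inside an ``r_local`` sphere around each LDP). The tree is then scored by

    S(T) = sum_n ( sum_{e in P_n} w'(e) )^2,

where P_1, P_2, ... are edge-disjoint density-weighted longest paths and
w'(e) = w(e) * min(endpoint densities). A tabu search perturbs the tree by
delete/add edge swaps (keeping total length within 1% of the MST's) to
maximize S; the longest path of the best tree is what the sequence is
threaded onto.
"""

from __future__ import annotations

import logging
import random
from collections import deque
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Edge",
    "SkeletonTree",
    "admissible_edges",
    "build_mst",
    "k_longest_paths",
    "tree_score",
    "tabu_refine",
    "write_tree_pdb",
    "TABU_CAPACITY",
    "CANDIDATES_PER_ITER",
    "LENGTH_FACTOR",
    "DEFAULT_N_PATHS",
]

TABU_CAPACITY = 100        # bounded FIFO of forbidden moves
CANDIDATES_PER_ITER = 30   # delete/add swaps sampled per tabu iteration
LENGTH_FACTOR = 1.01       # allowed total length relative to the MST
DEFAULT_N_PATHS = 100      # paths entering the tree score


@dataclass(frozen=True)
class Edge:
    """Tree edge between two LDP ids with length w and density cost w'."""

    a: int
    b: int
    w: float        # Euclidean length, Angstrom
    w_cost: float   # w * min(theta of the endpoints)

    def __post_init__(self):
        if self.a == self.b:
            raise ValueError("edge endpoints must be distinct")
        if self.a > self.b:
            object.__setattr__(self, "a", self.b)
            object.__setattr__(self, "b", self.a)

    @property
    def key(self) -> tuple:
        return (self.a, self.b)


class SkeletonTree:
    """A spanning tree (or forest component) over LDP ids."""

    def __init__(self, vertices, edges):
        self.vertices = sorted(vertices)
        self.edges = sorted(edges, key=lambda e: e.key)
        if len(self.edges) != len(self.vertices) - 1:
            raise ValueError("edge count must be vertex count - 1")
        self._adj = None
        if self.vertices and not self._connected():
            raise ValueError("tree must be connected")

    @property
    def adjacency(self) -> dict:
        if self._adj is None:
            adj = {v: {} for v in self.vertices}
            for e in self.edges:
                adj[e.a][e.b] = e
                adj[e.b][e.a] = e
            self._adj = adj
        return self._adj

    def _connected(self) -> bool:
        seen = {self.vertices[0]}
        stack = [self.vertices[0]]
        adj = self.adjacency
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(self.vertices)

    @property
    def total_length(self) -> float:
        return float(sum(e.w for e in self.edges))

    def replaced(self, e_del: Edge, e_add: Edge) -> "SkeletonTree":
        """New tree with one edge swapped (validity checked by constructor)."""
        edges = [e for e in self.edges if e.key != e_del.key] + [e_add]
        return SkeletonTree(self.vertices, edges)

    def edge_keys(self) -> set:
        return {e.key for e in self.edges}


def _ldp_arrays(ldps):
    ids = np.array([l.id for l in ldps])
    pos = np.array([l.position for l in ldps])
    theta = np.array([l.theta_raw for l in ldps])
    return ids, pos, theta


def _candidate_edges(ldps) -> list:
    """All grid-adjacent LDP pairs as weighted edges."""
    by_id = {l.id: l for l in ldps}
    edges = []
    for l in ldps:
        for other in l.adjacent_ids:
            if other > l.id:
                o = by_id[other]
                w = float(np.linalg.norm(l.position - o.position))
                edges.append(Edge(l.id, other, w,
                                  w * min(l.theta_raw, o.theta_raw)))
    return sorted(edges, key=lambda e: (e.w, e.key))


def _kruskal(nodes, edges) -> list:
    """MST forest by Kruskal with deterministic (w, endpoint) tie-breaking."""
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    out = []
    for e in sorted(edges, key=lambda e: (e.w, e.key)):
        ra, rb = find(e.a), find(e.b)
        if ra != rb:
            parent[rb] = ra
            out.append(e)
    return out


def admissible_edges(ldps, r_local: float) -> list:
    """Union of local-MST edges: the edge set global tree building may use.

    For every LDP, the MST (forest) of the adjacency subgraph induced by
    LDPs within ``r_local`` of it is computed; an edge is admissible iff it
    appears in at least one local MST. Restricting the global tree to these
    edges preserves locally optimal connectivity.
    """
    if r_local <= 0:
        raise ValueError("r_local must be positive")
    candidates = _candidate_edges(ldps)
    if not candidates:
        raise ValueError("LDP adjacency graph has no edges")
    from scipy.spatial import cKDTree
    ids, pos, _ = _ldp_arrays(ldps)
    kdt = cKDTree(pos)
    admissible: dict = {}
    for i, l in enumerate(ldps):
        ball = set(ids[j] for j in kdt.query_ball_point(pos[i], r_local))
        local = [e for e in candidates if e.a in ball and e.b in ball]
        for e in _kruskal(ball, local):
            admissible[e.key] = e
    return sorted(admissible.values(), key=lambda e: e.key)


def build_mst(ldps, admissible) -> SkeletonTree:
    """Global MST over the admissible edges (largest component if split)."""
    nodes = sorted(l.id for l in ldps)
    forest = _kruskal(nodes, admissible)
    # identify components
    comp = {v: v for v in nodes}

    def find(v):
        while comp[v] != v:
            comp[v] = comp[comp[v]]
            v = comp[v]
        return v

    for e in forest:
        comp[find(e.b)] = find(e.a)
    groups: dict = {}
    for v in nodes:
        groups.setdefault(find(v), []).append(v)
    largest = max(groups.values(), key=lambda g: (len(g), -min(g)))
    if len(largest) < len(nodes):
        sizes = sorted((len(g) for g in groups.values()), reverse=True)
        logger.warning("admissible graph disconnected; tracing largest of "
                       "components with sizes %s", sizes)
    keep = set(largest)
    edges = [e for e in forest if e.a in keep]
    return SkeletonTree(largest, edges)


# ---------------------------------------------------------------------------
# Longest paths and the tree score
# ---------------------------------------------------------------------------

def _farthest(adj: dict, start: int):
    """Farthest node from start by w' distance (double-sweep primitive).

    Returns (node, dist, parents). Ties broken by smaller node id.
    """
    dist = {start: 0.0}
    parent = {start: None}
    stack = [start]
    while stack:
        u = stack.pop()
        for v, e in adj[u].items():
            if v not in dist:
                dist[v] = dist[u] + e.w_cost
                parent[v] = u
                stack.append(v)
    far = min(dist, key=lambda v: (-dist[v], v))
    return far, dist[far], parent


def _component_nodes(adj: dict, start: int) -> list:
    seen = {start}
    stack = [start]
    while stack:
        for v in adj[stack.pop()]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return sorted(seen)


def k_longest_paths(tree: SkeletonTree, n_paths: int = DEFAULT_N_PATHS) -> list:
    """Edge-disjoint density-weighted longest paths P_1 >= P_2 >= ...

    P_1 maximizes the sum of w' over any simple path in the tree (found by
    the two-sweep method, valid for non-negative weights); each later path
    is the longest in the forest left after removing all previous paths'
    edges. Returns a list of (vertex_list, total_w_cost, edge_list),
    stopping early once no edges remain.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    adj = {u: dict(nbrs) for u, nbrs in tree.adjacency.items()}
    paths = []
    for _ in range(n_paths):
        # find the global best path over all remaining components
        seen: set = set()
        best = None
        for v in tree.vertices:
            if v in seen or not adj[v]:
                continue
            comp = _component_nodes(adj, v)
            seen.update(comp)
            u, _, _ = _farthest(adj, comp[0])
            far, total, parent = _farthest(adj, u)
            if best is None or total > best[1] + 1e-12:
                node, chain = far, []
                while node is not None:
                    chain.append(node)
                    node = parent[node]
                best = (chain[::-1], total)
        if best is None:
            break
        verts, total = best
        edges = [adj[a][b] for a, b in zip(verts, verts[1:])]
        for a, b in zip(verts, verts[1:]):
            del adj[a][b]
            del adj[b][a]
        paths.append((verts, total, edges))
    return paths


def tree_score(tree: SkeletonTree, n_paths: int = DEFAULT_N_PATHS) -> float:
    """S(T): sum of squared w' totals of the edge-disjoint longest paths."""
    return float(sum(total * total
                     for _, total, _ in k_longest_paths(tree, n_paths)))


# ---------------------------------------------------------------------------
# Tabu search
# ---------------------------------------------------------------------------

class _TabuList:
    """Bounded FIFO of move identities (unordered edge-key pairs)."""

    def __init__(self, capacity: int = TABU_CAPACITY):
        self.fifo = deque()
        self.counts: dict = {}
        self.capacity = capacity

    def push(self, move: frozenset) -> None:
        self.fifo.append(move)
        self.counts[move] = self.counts.get(move, 0) + 1
        while len(self.fifo) > self.capacity:
            old = self.fifo.popleft()
            self.counts[old] -= 1
            if self.counts[old] == 0:
                del self.counts[old]

    def __contains__(self, move: frozenset) -> bool:
        return move in self.counts


def _split(tree: SkeletonTree, e_del: Edge) -> set:
    """Vertices on e_del.a's side after deleting e_del."""
    seen = {e_del.a}
    stack = [e_del.a]
    adj = tree.adjacency
    while stack:
        u = stack.pop()
        for v, e in adj[u].items():
            if e.key == e_del.key or v in seen:
                continue
            seen.add(v)
            stack.append(v)
    return seen


def tabu_refine(tree: SkeletonTree, admissible, d_keep: float, n_iter: int,
                seed: int, n_paths: int = DEFAULT_N_PATHS,
                n_candidates: int = CANDIDATES_PER_ITER,
                length_factor: float = LENGTH_FACTOR,
                tabu_capacity: int = TABU_CAPACITY) -> SkeletonTree:
    """Refine a spanning tree by tabu-searched edge swaps, maximizing S(T).

    Per iteration, ``n_candidates`` moves are sampled: delete an edge longer
    than ``d_keep`` (uniformly), re-add an admissible edge across the cut
    (uniformly among those keeping the total length within
    ``length_factor`` x the starting tree's), skipping moves on the tabu
    list. The best-scoring candidate replaces the incumbent only if it
    strictly improves S; the applied move and its reverse enter the FIFO
    tabu list. The best tree ever seen is returned.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = random.Random(seed)
    w_limit = length_factor * tree.total_length
    admissible = sorted(admissible, key=lambda e: e.key)
    tabu = _TabuList(tabu_capacity)
    incumbent, inc_score = tree, tree_score(tree, n_paths)
    best, best_score = incumbent, inc_score
    noop_count = 0
    for _ in range(n_iter):
        deletable = [e for e in incumbent.edges if e.w > d_keep]
        candidates = []
        if deletable:
            tree_keys = incumbent.edge_keys()
            w_total = incumbent.total_length
            split_cache: dict = {}
            for _ in range(n_candidates):
                e_del = rng.choice(deletable)
                if e_del.key not in split_cache:
                    split_cache[e_del.key] = _split(incumbent, e_del)
                side = split_cache[e_del.key]
                valid = [e for e in admissible
                         if ((e.a in side) != (e.b in side))
                         and e.key not in tree_keys
                         and w_total - e_del.w + e.w <= w_limit + 1e-9
                         and frozenset((e_del.key, e.key)) not in tabu]
                if not valid:
                    continue
                candidates.append((e_del, rng.choice(valid)))
        if not candidates:
            noop_count += 1
            continue
        best_cand = None
        for e_del, e_add in candidates:
            t2 = incumbent.replaced(e_del, e_add)
            s2 = tree_score(t2, n_paths)
            if best_cand is None or s2 > best_cand[0] + 1e-12:
                best_cand = (s2, t2, e_del, e_add)
        s2, t2, e_del, e_add = best_cand
        if s2 > inc_score + 1e-12:
            incumbent, inc_score = t2, s2
            move = frozenset((e_del.key, e_add.key))
            tabu.push(move)   # the move ...
            tabu.push(move)   # ... and its reverse (same unordered identity)
            if inc_score > best_score:
                best, best_score = incumbent, inc_score
    if noop_count:
        logger.debug("tabu search: %d/%d iterations had no admissible move",
                     noop_count, n_iter)
    return best


def write_tree_pdb(path: str, tree: SkeletonTree, ldps) -> None:
    """Export a tree as pseudo-atoms with CONECT records (visualization)."""
    by_id = {l.id: l for l in ldps}
    serial = {v: i + 1 for i, v in enumerate(tree.vertices)}
    with open(path, "w") as fh:
        for v in tree.vertices:
            p = by_id[v].position
            fh.write("HETATM{:5d}  C   LDP A{:4d}    "
                     "{:8.3f}{:8.3f}{:8.3f}{:6.2f}{:6.2f}           C\n".format(
                         serial[v], serial[v] % 10000, p[0], p[1], p[2], 1.0,
                         by_id[v].theta_norm * 100))
        for e in tree.edges:
            fh.write("CONECT{:5d}{:5d}\n".format(serial[e.a], serial[e.b]))
        fh.write("END\n")
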