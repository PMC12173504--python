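"""Two-layer hypergraphs: pairwise edges plus triangles, with tunable overlap.

A population is a hypergraph whose hyperedges are restricted to sizes 2 and 3:
a *pairwise layer* ``E_pair`` of unordered node pairs and a *triangle layer*
``E_tri`` of unordered node triples.  The topological overlap ``omega`` is the
fraction of pairwise edges that also appear as a projected side of some
triangle.  A three-regular simplicial complex (every triangle side present as a
pairwise edge, and nothing else) has ``omega = 1``; fully disjoint layers have
``omega = 0``.

Overlap is tuned downward from the simplicial-complex endpoint by degree
preserving *criss-cross* double edge swaps on the pairwise layer only, with
both layers kept connected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

Edge = tuple[int, int]
Triangle = tuple[int, int, int]

__all__ = [
    "Hypergraph",
    "OverlapReport",
    "SwapRejected",
    "RewireError",
    "build_full_overlap",
    "project_triangles",
    "compute_overlap",
    "crisscross_swap",
    "rewire_to_overlap",
    "co_players",
    "read_hypergraph",
    "write_hypergraph",
]


class SwapRejected(Exception):
    """A candidate criss-cross swap violates its preconditions.

    This is a rejection signal for the caller's sampling loop, not a fatal
    error: the caller is expected to draw a fresh candidate pair of edges.
    """


class RewireError(RuntimeError):
    """Rewiring could not reach the requested overlap within the swap budget."""


def _norm_edge(i: int, j: int) -> Edge:
    return (i, j) if i < j else (j, i)


def _norm_triangle(i: int, j: int, k: int) -> Triangle:
    return tuple(sorted((i, j, k)))  # type: ignore[return-value]


@dataclass
class Hypergraph:
    """Nodes ``0..n_nodes-1`` with a pairwise-edge layer and a triangle layer.

    ``pair_edges`` holds unordered pairs as sorted tuples, ``triangles``
    unordered triples as sorted tuples.  Pairwise adjacency sets are maintained
    incrementally so swaps and payoff sweeps stay cheap.
    """

    n_nodes: int
    pair_edges: set[Edge] = field(default_factory=set)
    triangles: set[Triangle] = field(default_factory=set)
    _pair_adj: list[set[int]] = field(init=False, repr=False)
    _node_triangles: list[list[Triangle]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.pair_edges = {_norm_edge(*e) for e in self.pair_edges}
        self.triangles = {_norm_triangle(*t) for t in self.triangles}
        self.validate()
        self._rebuild_adjacency()

    def _rebuild_adjacency(self) -> None:
        self._pair_adj = [set() for _ in range(self.n_nodes)]
        for i, j in self.pair_edges:
            self._pair_adj[i].add(j)
            self._pair_adj[j].add(i)
        self._node_triangles = [[] for _ in range(self.n_nodes)]
        for t in sorted(self.triangles):
            for v in t:
                self._node_triangles[v].append(t)

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on violation."""
        if self.n_nodes <= 0:
            raise ValueError("hypergraph needs at least one node")
        for i, j in self.pair_edges:
            if i == j:
                raise ValueError(f"self-loop on node {i}")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"edge ({i},{j}) out of node range")
        for t in self.triangles:
            if len(set(t)) != 3:
                raise ValueError(f"triangle {t} has repeated nodes")
            if not all(0 <= v < self.n_nodes for v in t):
                raise ValueError(f"triangle {t} out of node range")
        # Two triangles sharing two nodes would project the same pair twice.
        tris = sorted(self.triangles)
        for a, b in itertools.combinations(tris, 2):
            if len(set(a) & set(b)) >= 2:
                raise ValueError(f"triangles {a} and {b} share two nodes")

    # -- queries ----------------------------------------------------------

    def pair_neighbors(self, node: int) -> set[int]:
        self._check_node(node)
        return set(self._pair_adj[node])

    def triangle_partners(self, node: int) -> set[int]:
        self._check_node(node)
        out: set[int] = set()
        for t in self._node_triangles[node]:
            out.update(v for v in t if v != node)
        return out

    def triangles_of(self, node: int) -> list[Triangle]:
        self._check_node(node)
        return list(self._node_triangles[node])

    def pair_degree(self, node: int) -> int:
        self._check_node(node)
        return len(self._pair_adj[node])

    def tri_degree(self, node: int) -> int:
        self._check_node(node)
        return len(self._node_triangles[node])

    def _check_node(self, node: int) -> None:
        if not (0 <= node < self.n_nodes):
            raise ValueError(f"unknown node {node}")

    def copy(self) -> "Hypergraph":
        return Hypergraph(self.n_nodes, set(self.pair_edges), set(self.triangles))

    # -- layer connectivity ------------------------------------------------

    def pair_layer_connected(self) -> bool:
        """Breadth-first reachability over pairwise edges only."""
        return _bfs_covers(self.n_nodes, self._pair_adj)

    def tri_layer_connected(self) -> bool:
        """Breadth-first reachability walking through triangles only."""
        adj: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for a, b, c in self.triangles:
            adj[a].update((b, c))
            adj[b].update((a, c))
            adj[c].update((a, b))
        return _bfs_covers(self.n_nodes, adj)

    # -- array export for the compiled engine ------------------------------

    def to_arrays(self) -> dict[str, np.ndarray]:
        """Pack the structure into padded integer arrays for the fast engine."""
        n = self.n_nodes
        max_deg = max((len(a) for a in self._pair_adj), default=0)
        max_ktri = max((len(t) for t in self._node_triangles), default=0)
        tris = np.array(sorted(self.triangles), dtype=np.int32).reshape(-1, 3)
        tri_index = {t: i for i, t in enumerate(sorted(self.triangles))}
        pair_nbrs = np.zeros((n, max(max_deg, 1)), dtype=np.int32)
        pair_deg = np.zeros(n, dtype=np.int32)
        node_tris = np.zeros((n, max(max_ktri, 1)), dtype=np.int32)
        node_ktri = np.zeros(n, dtype=np.int32)
        for i in range(n):
            nbrs = sorted(self._pair_adj[i])
            pair_deg[i] = len(nbrs)
            pair_nbrs[i, : len(nbrs)] = nbrs
            ts = self._node_triangles[i]
            node_ktri[i] = len(ts)
            for s, t in enumerate(ts):
                node_tris[i, s] = tri_index[t]
        max_union = 1
        unions = []
        for i in range(n):
            u = sorted(self._pair_adj[i] | self.triangle_partners(i))
            unions.append(u)
            max_union = max(max_union, len(u))
        union = np.zeros((n, max_union), dtype=np.int32)
        union_len = np.zeros(n, dtype=np.int32)
        for i, u in enumerate(unions):
            union_len[i] = len(u)
            union[i, : len(u)] = u
        return {
            "pair_nbrs": pair_nbrs,
            "pair_deg": pair_deg,
            "triangles": tris,
            "node_tris": node_tris,
            "node_ktri": node_ktri,
            "union": union,
            "union_len": union_len,
        }


def _bfs_covers(n: int, adj: list[set[int]]) -> bool:
    if n == 1:
        return True
    seen = [False] * n
    stack = [0]
    seen[0] = True
    count = 1
    while stack:
        v = stack.pop()
        for u in adj[v]:
            if not seen[u]:
                seen[u] = True
                count += 1
                stack.append(u)
    return count == n


@dataclass(frozen=True)
class OverlapReport:
    """Topological overlap of the pairwise layer with the triangle projection."""

    omega: float
    n_shared_edges: int
    n_pair_edges: int

    @property
    def granularity(self) -> float:
        """Resolution of achievable overlap values: one pairwise edge."""
        return 1.0 / self.n_pair_edges


def project_triangles(h: Hypergraph) -> set[Edge]:
    """All unordered pairs spanned by some triangle (the one-skeleton of E_tri)."""
    out: set[Edge] = set()
    for a, b, c in h.triangles:
        out.add(_norm_edge(a, b))
        out.add(_norm_edge(a, c))
        out.add(_norm_edge(b, c))
    return out


def compute_overlap(h: Hypergraph) -> OverlapReport:
    """Fraction of pairwise edges that coincide with a projected triangle side."""
    if not h.pair_edges:
        raise ValueError("overlap undefined: pairwise layer is empty")
    proj = project_triangles(h)
    shared = len(h.pair_edges & proj)
    return OverlapReport(
        omega=shared / len(h.pair_edges),
        n_shared_edges=shared,
        n_pair_edges=len(h.pair_edges),
    )


def co_players(h: Hypergraph, node: int) -> tuple[set[int], set[int], set[int]]:
    """Pairwise neighbours, triangle partners, and their de-duplicated union.

    At full overlap with pair degree ``2*k_tri`` the union collapses onto the
    pairwise neighbourhood; at zero overlap a node with degrees (k_pair, k_tri)
    can meet up to ``k_pair + 2*k_tri`` distinct co-players.
    """
    pair = h.pair_neighbors(node)
    tri = h.triangle_partners(node)
    return pair, tri, pair | tri


def build_full_overlap(
    n_nodes: int, k_pair: int, k_tri: int, seed: int | None = None,
    max_restarts: int = 1000,
) -> Hypergraph:
    """Random-regular hypergraph at ``omega = 1`` (three-regular simplicial complex).

    Every node sits in exactly ``k_tri`` triangles; the pairwise layer is set to
    the triangle projection, which makes every pairwise degree exactly
    ``2*k_tri`` — hence the requirement ``k_pair == 2*k_tri``.

    Triangles are sampled with configuration-model stub matching: each node
    contributes ``k_tri`` stubs, the stub list is shuffled and cut into
    consecutive triples.  A matching is rejected (and restarted) if any triple
    repeats a node, duplicates an existing triangle, shares two nodes with one,
    or leaves a layer disconnected.
    """
    if k_pair != 2 * k_tri:
        raise ValueError(
            f"full overlap requires k_pair == 2*k_tri, got k_pair={k_pair}, k_tri={k_tri}"
        )
    if (n_nodes * k_tri) % 3 != 0:
        raise ValueError(
            f"n_nodes*k_tri = {n_nodes * k_tri} must be divisible by 3 to tile triangles"
        )
    if n_nodes < 3 * k_tri + 1:
        raise ValueError(f"need n_nodes >= {3 * k_tri + 1} for a simple construction")
    rng = np.random.default_rng(seed)
    stubs = np.repeat(np.arange(n_nodes), k_tri)
    for _ in range(max_restarts):
        rng.shuffle(stubs)
        triangles: set[Triangle] = set()
        pair_seen: set[Edge] = set()
        ok = True
        for s in range(0, len(stubs), 3):
            a, b, c = int(stubs[s]), int(stubs[s + 1]), int(stubs[s + 2])
            if a == b or b == c or a == c:
                ok = False
                break
            t = _norm_triangle(a, b, c)
            sides = (_norm_edge(a, b), _norm_edge(a, c), _norm_edge(b, c))
            # A repeated side means this triple duplicates a triangle or
            # shares two nodes with one already placed.
            if t in triangles or any(e in pair_seen for e in sides):
                ok = False
                break
            triangles.add(t)
            pair_seen.update(sides)
        if not ok:
            continue
        h = Hypergraph(n_nodes, pair_edges=pair_seen, triangles=triangles)
        if not h.tri_layer_connected() or not h.pair_layer_connected():
            continue
        return h
    raise RuntimeError(
        f"stub matching failed after {max_restarts} restarts "
        f"(n_nodes={n_nodes}, k_tri={k_tri}); constraints: simple triples, "
        "no two triangles sharing a pair, connected layers"
    )


def crisscross_swap(h: Hypergraph, edge_ab: Edge, edge_cd: Edge) -> Hypergraph:
    """Degree-preserving double swap: edges A-B, C-D become A-D, B-C.

    Preconditions (raise :class:`SwapRejected` when violated so the caller can
    draw a fresh candidate): the four endpoints are distinct, both edges exist,
    and there are no other pairwise links between {A,B} and {C,D}.  Triangles
    are never touched.  Mutates ``h`` in place and returns it.
    """
    a, b = edge_ab
    c, d = edge_cd
    if len({a, b, c, d}) != 4:
        raise SwapRejected("endpoints not distinct")
    ab, cd = _norm_edge(a, b), _norm_edge(c, d)
    if ab not in h.pair_edges or cd not in h.pair_edges:
        raise SwapRejected("edge not present in pairwise layer")
    for x in (a, b):
        for y in (c, d):
            if y in h._pair_adj[x]:
                raise SwapRejected(f"existing link {x}-{y} between the edge pairs")
    h.pair_edges.discard(ab)
    h.pair_edges.discard(cd)
    h.pair_edges.add(_norm_edge(a, d))
    h.pair_edges.add(_norm_edge(b, c))
    h._pair_adj[a].discard(b)
    h._pair_adj[b].discard(a)
    h._pair_adj[c].discard(d)
    h._pair_adj[d].discard(c)
    h._pair_adj[a].add(d)
    h._pair_adj[d].add(a)
    h._pair_adj[b].add(c)
    h._pair_adj[c].add(b)
    return h


def rewire_to_overlap(
    h: Hypergraph,
    target_omega: float,
    tolerance: float | None = None,
    max_swaps: int | None = None,
    seed: int | None = None,
) -> Hypergraph:
    """Tune the pairwise layer to ``|omega - target_omega| <= tolerance``.

    Works on a copy; the input hypergraph is left untouched.  Candidate edge
    pairs are drawn uniformly; a candidate is accepted only if the swap does not
    move the overlap away from the target (blind swapping instead relaxes to the
    coincidental overlap of a random regular graph, which for small targets is
    out of reach).  Every committed swap keeps the pairwise layer connected —
    disconnecting swaps are reverted — and the triangle layer is bit-identical
    to the input.
    """
    if not (0.0 <= target_omega <= 1.0):
        raise ValueError("target_omega must be in [0, 1]")
    out = h.copy()
    if not out.pair_edges:
        raise ValueError("cannot rewire an empty pairwise layer")
    n_edges = len(out.pair_edges)
    if tolerance is None:
        tolerance = 1.0 / n_edges
    if tolerance < 1.0 / n_edges:
        raise ValueError(
            f"tolerance {tolerance} finer than the overlap granularity 1/{n_edges}"
        )
    if max_swaps is None:
        max_swaps = 100 * n_edges
    if not out.tri_layer_connected():
        raise ValueError("triangle layer must be connected before rewiring")
    rng = np.random.default_rng(seed)
    proj = project_triangles(out)
    shared = len(out.pair_edges & proj)
    target_shared = target_omega * n_edges

    edge_list = sorted(out.pair_edges)
    edge_pos = {e: i for i, e in enumerate(edge_list)}

    def replace_edge(old: Edge, new: Edge) -> None:
        i = edge_pos.pop(old)
        edge_list[i] = new
        edge_pos[new] = i

    best = shared
    for _ in range(max_swaps):
        if abs(shared - target_shared) <= tolerance * n_edges + 1e-9:
            return out
        i, j = rng.integers(0, n_edges, size=2)
        if i == j:
            continue
        e1, e2 = edge_list[i], edge_list[j]
        a, b = e1
        c, d = e2
        # Orient the swap at random: A-B, C-D -> A-D, B-C; flipping one edge
        # gives the alternative pairing A-C, B-D.
        if rng.random() < 0.5:
            c, d = d, c
        new1, new2 = _norm_edge(a, d), _norm_edge(b, c)
        delta = (
            (new1 in proj) + (new2 in proj) - (e1 in proj) - (e2 in proj)
        )
        if abs(shared + delta - target_shared) > abs(shared - target_shared):
            continue
        try:
            crisscross_swap(out, (a, b), (c, d))
        except SwapRejected:
            continue
        if not out.pair_layer_connected():
            # revert: swap((D,A),(B,C)) restores D-C and A-B
            crisscross_swap(out, (d, a), (b, c))
            continue
        replace_edge(e1, new1)
        replace_edge(e2, new2)
        shared += delta
        best = min(best, shared, key=lambda s: abs(s - target_shared))
    if abs(shared - target_shared) <= tolerance * n_edges + 1e-9:
        return out
    raise RewireError(
        f"target omega {target_omega} not reached within {max_swaps} swaps; "
        f"best omega achieved {best / n_edges:.4f}"
    )


# -- plain-text serialization ----------------------------------------------


def write_hypergraph(h: Hypergraph, path: str) -> None:
    """Write the plain-text layer lists: `# nodes N`, then `E i j` / `T i j k`.

    Edges and triangles are emitted sorted so output diffs are reproducible.
    """
    with open(path, "w") as fh:
        fh.write(f"# nodes {h.n_nodes}\n")
        for i, j in sorted(h.pair_edges):
            fh.write(f"E {i} {j}\n")
        for i, j, k in sorted(h.triangles):
            fh.write(f"T {i} {j} {k}\n")


def read_hypergraph(path: str) -> Hypergraph:
    """Read the plain-text format written by :func:`write_hypergraph`."""
    n_nodes: int | None = None
    pair_edges: set[Edge] = set()
    triangles: set[Triangle] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if parts[0] == "#":
                if len(parts) == 3 and parts[1] == "nodes":
                    n_nodes = int(parts[2])
                continue
            if parts[0] == "E" and len(parts) == 3:
                pair_edges.add(_norm_edge(int(parts[1]), int(parts[2])))
            elif parts[0] == "T" and len(parts) == 4:
                triangles.add(_norm_triangle(int(parts[1]), int(parts[2]), int(parts[3])))
            else:
                raise ValueError(f"{path}:{lineno}: unrecognized line {line!r}")
    if n_nodes is None:
        raise ValueError(f"{path}: missing '# nodes N' header")
    return Hypergraph(n_nodes, pair_edges, triangles)
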