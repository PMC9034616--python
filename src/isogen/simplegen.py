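"""Stage 1: isomorph-free generation of connected simple skeletons.

One labelled representative of every isomorphism class of connected simple
graphs on ``n`` vertices, with edge count inside the budget range and every
degree at most the maximum valence of the formula, is produced by McKay-style
canonical augmentation:

* trees are grown vertex-by-vertex (attach a new leaf, accept the child only
  if the new leaf lies in the canonically-chosen deletable-leaf orbit);
* graphs with more edges are grown edge-by-edge from spanning trees (accept
  only if the new edge lies in the canonically-chosen deletable — i.e.
  non-bridge — edge orbit).

The canonical choice is made in two steps: a cheap isomorphism-invariant
score (sorted endpoint degrees for edges, neighbour degree for leaves)
pre-filters the candidates, and the BLISS canonical labelling breaks ties.
Because both the score and the candidate sets are isomorphism-invariant,
exactly one augmentation per child class is accepted, so nothing has to be
stored or compared against previous output: generation is memoryless and
streams each graph to stage 2 as soon as it is produced.

Accepted graphs are relabelled to their canonical form before being used as
parents, which makes the emitted labelled graphs a deterministic, path- and
order-independent choice of class representatives.

Degree caps and the stage-1 structural filters (planarity, 5-cycle upper
bound, B9) are all preserved under edge deletion, so pruning a violating
graph also prunes all of its descendants — filtering this early is what makes
the flags cheap.
"""

from __future__ import annotations

from typing import Iterator, Sequence

import igraph as ig

from .filters import FilterConfig, stage1_emit_ok, stage1_prunable
from .formula import EdgeBudget

__all__ = ["SimpleGraph", "generate_simple_graphs", "is_canonical_member"]

Edge = tuple[int, int]


class SimpleGraph:
    """A connected hydrogen-suppressed skeleton.

    Vertices are ``0..n-1``; ``edges`` is the fixed canonical edge order
    (pairs ``(u, v)`` with ``u < v``, sorted lexicographically).  Stage-3
    multiplicity lists index into this order.
    """

    __slots__ = ("n", "edges", "_degrees", "_adj")

    def __init__(self, n: int, edges: Sequence[Edge]):
        norm = sorted((a, b) if a < b else (b, a) for a, b in edges)
        if any(a == b for a, b in norm):
            raise ValueError("loops are not allowed")
        if len(set(norm)) != len(norm):
            raise ValueError("parallel edges are not allowed")
        if norm and (norm[0][0] < 0 or max(b for _, b in norm) >= n):
            raise ValueError("edge endpoint out of range")
        self.n = n
        self.edges: tuple[Edge, ...] = tuple(norm)
        self._degrees: tuple[int, ...] | None = None
        self._adj: dict[int, tuple[int, ...]] | None = None

    @property
    def degrees(self) -> tuple[int, ...]:
        if self._degrees is None:
            d = [0] * self.n
            for a, b in self.edges:
                d[a] += 1
                d[b] += 1
            self._degrees = tuple(d)
        return self._degrees

    @property
    def adjacency(self) -> dict[int, tuple[int, ...]]:
        if self._adj is None:
            adj: dict[int, list[int]] = {v: [] for v in range(self.n)}
            for a, b in self.edges:
                adj[a].append(b)
                adj[b].append(a)
            self._adj = {v: tuple(sorted(ws)) for v, ws in adj.items()}
        return self._adj

    def neighbors(self, v: int) -> tuple[int, ...]:
        return self.adjacency[v]

    def igraph(self) -> ig.Graph:
        return ig.Graph(self.n, list(self.edges))

    def is_connected(self) -> bool:
        if self.n <= 1:
            return True
        seen = {0}
        stack = [0]
        while stack:
            v = stack.pop()
            for w in self.neighbors(v):
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == self.n

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SimpleGraph)
            and self.n == other.n
            and self.edges == other.edges
        )

    def __hash__(self) -> int:
        return hash((self.n, self.edges))

    def __repr__(self) -> str:
        return f"SimpleGraph(n={self.n}, edges={list(self.edges)})"


def is_canonical_member(g: SimpleGraph) -> bool:
    """True iff ``g`` is the designated labelled representative of its class.

    The representative is the BLISS-canonical labelling, which is exactly the
    labelling in which :func:`generate_simple_graphs` emits every graph.
    """
    G = g.igraph()
    p = G.canonical_permutation()
    canon = sorted(
        (p[a], p[b]) if p[a] < p[b] else (p[b], p[a]) for a, b in g.edges
    )
    return tuple(canon) == g.edges


def _vertex_orbit_reps(vertices: Sequence[int], gens: list[list[int]]) -> list[int]:
    seen: set[int] = set()
    reps = []
    for v in vertices:
        if v in seen:
            continue
        reps.append(v)
        seen.add(v)
        stack = [v]
        while stack:
            a = stack.pop()
            for g in gens:
                x = g[a]
                if x not in seen:
                    seen.add(x)
                    stack.append(x)
    return reps


def _pair_orbit_reps(pairs: Sequence[Edge], gens: list[list[int]]) -> list[Edge]:
    seen: set[Edge] = set()
    reps = []
    for pr in pairs:
        if pr in seen:
            continue
        reps.append(pr)
        seen.add(pr)
        stack = [pr]
        while stack:
            a, b = stack.pop()
            for g in gens:
                x, y = g[a], g[b]
                q = (x, y) if x < y else (y, x)
                if q not in seen:
                    seen.add(q)
                    stack.append(q)
    return reps


def _accept_leaf(Y: ig.Graph, lv: int):
    """Parent-rule test after attaching the new leaf ``lv``.

    Returns ``(accepted, canonical_permutation_or_None)``.
    """
    degs = Y.degree()
    adj = Y.get_adjlist()
    best_s = -1
    cands: list[int] = []
    for x in range(Y.vcount()):
        if degs[x] != 1:
            continue
        s = degs[adj[x][0]]
        if s > best_s:
            best_s = s
            cands = [x]
        elif s == best_s:
            cands.append(x)
    if degs[adj[lv][0]] < best_s:
        return False, None
    p = Y.canonical_permutation()
    best_img = -1
    best_l = -1
    for x in cands:
        if p[x] > best_img:
            best_img = p[x]
            best_l = x
    if best_l == lv:
        return True, p
    gens = Y.automorphism_group()
    if not gens:
        return False, None
    seen = {lv}
    stack = [lv]
    while stack:
        a = stack.pop()
        for g in gens:
            x = g[a]
            if x == best_l:
                return True, p
            if x not in seen:
                seen.add(x)
                stack.append(x)
    return False, None


def _accept_edge(Y: ig.Graph, u: int, v: int):
    """Parent-rule test after adding the edge ``(u, v)`` (last edge index)."""
    el = Y.get_edgelist()
    degs = Y.degree()
    bridge_set = set(Y.bridges())
    ei = len(el) - 1
    best_s: tuple[int, int] | None = None
    cands: list[int] = []
    for i, (a, b) in enumerate(el):
        if i in bridge_set:
            continue
        da, db = degs[a], degs[b]
        s = (da, db) if da >= db else (db, da)
        if best_s is None or s > best_s:
            best_s = s
            cands = [i]
        elif s == best_s:
            cands.append(i)
    # the new edge closes a cycle, hence is never a bridge and best_s covers it
    da, db = degs[u], degs[v]
    se = (da, db) if da >= db else (db, da)
    if se < best_s:  # type: ignore[operator]
        return False, None
    p = Y.canonical_permutation()
    best_img: tuple[int, int] | None = None
    best_i = -1
    for i in cands:
        a, b = el[i]
        pa, pb = p[a], p[b]
        im = (pa, pb) if pa >= pb else (pb, pa)
        if best_img is None or im > best_img:
            best_img = im
            best_i = i
    if best_i == ei:
        return True, p
    gens = Y.automorphism_group()
    if not gens:
        return False, None
    ta, tb = el[best_i]
    target = (ta, tb) if ta < tb else (tb, ta)
    start = (u, v) if u < v else (v, u)
    seen = {start}
    stack = [start]
    while stack:
        a, b = stack.pop()
        for g in gens:
            x, y = g[a], g[b]
            q = (x, y) if x < y else (y, x)
            if q == target:
                return True, p
            if q not in seen:
                seen.add(q)
                stack.append(q)
    return False, None


def _generate_raw(
    n: int,
    min_edges: int,
    max_edges: int,
    max_degree: int,
    filters: FilterConfig | None = None,
) -> Iterator[tuple[SimpleGraph, ig.Graph]]:
    """Yield ``(SimpleGraph, live igraph handle)`` pairs.

    The igraph handle is valid until the next item is requested; callers that
    process each graph before advancing (the normal streaming pattern) may use
    it to avoid rebuilding the graph.
    """
    if n < 1 or min_edges > max_edges or max_edges < max(0, n - 1):
        return
    min_edges = max(min_edges, max(0, n - 1))
    active_filters = filters if filters is not None and filters.any_stage1() else None

    if n == 1:
        if min_edges <= 0:
            sg = SimpleGraph(1, ())
            if active_filters is None or (
                not stage1_prunable(sg, active_filters)
                and stage1_emit_ok(sg, active_filters)
            ):
                yield sg, ig.Graph(1)
        return
    if max_degree < 1:
        return

    def edge_stage(G: ig.Graph) -> Iterator[tuple[SimpleGraph, ig.Graph]]:
        m = G.ecount()
        edges = sorted(
            (a, b) if a < b else (b, a) for a, b in G.get_edgelist()
        )
        sg = SimpleGraph(n, edges)
        if active_filters is not None and stage1_prunable(sg, active_filters):
            return
        if m >= min_edges and (
            active_filters is None or stage1_emit_ok(sg, active_filters)
        ):
            yield sg, G
        if m >= max_edges:
            return
        degs = G.degree()
        present = set(sg.edges)
        cands = [
            (u, v)
            for u in range(n)
            if degs[u] < max_degree
            for v in range(u + 1, n)
            if degs[v] < max_degree and (u, v) not in present
        ]
        if not cands:
            return
        gens = G.automorphism_group()
        if gens:
            cands = _pair_orbit_reps(cands, gens)
        for u, v in cands:
            G.add_edge(u, v)
            ok, p = _accept_edge(G, u, v)
            if ok:
                yield from edge_stage(G.permute_vertices(p))
            G.delete_edges([G.ecount() - 1])

    def tree_stage(G: ig.Graph, k: int) -> Iterator[tuple[SimpleGraph, ig.Graph]]:
        if k == n:
            yield from edge_stage(G)
            return
        degs = G.degree()
        grow = [x for x in range(k) if degs[x] < max_degree]
        if not grow:
            return
        gens = G.automorphism_group()
        if gens:
            grow = _vertex_orbit_reps(grow, gens)
        for x in grow:
            G.add_vertex()
            G.add_edge(x, k)
            ok, p = _accept_leaf(G, k)
            if ok:
                yield from tree_stage(G.permute_vertices(p), k + 1)
            G.delete_vertices([k])

    yield from tree_stage(ig.Graph(2, [(0, 1)]), 2)


def generate_simple_graphs(
    budget: EdgeBudget,
    n: int,
    stage1_filters: FilterConfig | None = None,
) -> Iterator[SimpleGraph]:
    """Stream one representative per isomorphism class of connected simple
    graphs on ``n`` vertices within the edge budget.

    Graphs violating a stage-1 filter (planarity, the 5-cycle upper bound,
    B9) are pruned before emission — together with their whole augmentation
    subtree, since those violations persist under edge addition.
    """
    for sg, _ in _generate_raw(
        n, budget.min_edges, budget.max_edges, budget.max_degree, stage1_filters
    ):
        yield sg
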