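"""Shared fixtures and independent brute-force helpers.

The helpers here deliberately avoid igraph and the package's own canonical
machinery: class counting uses exhaustive permutation canonicalization, and
automorphism groups come from checking all n! bijections.  They are the
independent side of every dual-route check.
"""

from __future__ import annotations

from itertools import combinations, permutations

import pytest

from isogen.simplegen import SimpleGraph


@pytest.fixture
def c5() -> SimpleGraph:
    """The furan skeleton: a plain 5-cycle."""
    return SimpleGraph(5, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)])


@pytest.fixture
def star3() -> SimpleGraph:
    """Star with centre 3 and leaves 0, 1, 2 (one flower of size 3)."""
    return SimpleGraph(4, [(0, 3), (1, 3), (2, 3)])


@pytest.fixture
def path3() -> SimpleGraph:
    """Path 0-1-2: both leaves share neighbour 1, one flower {0, 2}."""
    return SimpleGraph(3, [(0, 1), (1, 2)])


def perm_edges(edges, perm):
    return tuple(
        sorted(
            (perm[a], perm[b]) if perm[a] < perm[b] else (perm[b], perm[a])
            for a, b in edges
        )
    )


def canon_edges(n, edges):
    """Minimum edge list over all vertex permutations (exhaustive)."""
    return min(perm_edges(edges, p) for p in permutations(range(n)))


def brute_connected_classes(n, min_e, max_e, max_deg):
    """Canonical forms of all connected simple graph classes in the budget."""
    pairs = list(combinations(range(n), 2))
    classes = set()
    for mask in range(1 << len(pairs)):
        edges = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
        if not (min_e <= len(edges) <= max_e):
            continue
        deg = [0] * n
        adj = [[] for _ in range(n)]
        for a, b in edges:
            deg[a] += 1
            deg[b] += 1
            adj[a].append(b)
            adj[b].append(a)
        if any(d > max_deg for d in deg):
            continue
        seen = {0}
        stack = [0]
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        if len(seen) != n:
            continue
        classes.add(canon_edges(n, edges))
    return classes


def brute_automorphisms(g: SimpleGraph):
    """All automorphisms of ``g`` by checking every vertex bijection."""
    edge_set = set(g.edges)
    deg = g.degrees
    out = []
    for p in permutations(range(g.n)):
        if any(deg[v] != deg[p[v]] for v in range(g.n)):
            continue
        if all(
            ((p[a], p[b]) if p[a] < p[b] else (p[b], p[a])) in edge_set
            for a, b in g.edges
        ):
            out.append(tuple(p))
    return out


def brute_canon_list(L, aut):
    """max over gamma in aut of gamma(L), by direct application."""
    best = tuple(L)
    for p in aut:
        img = [None] * len(L)
        for v, lab in zip(p, L):
            img[v] = lab
        img = tuple(img)
        if img > best:
            best = img
    return best
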