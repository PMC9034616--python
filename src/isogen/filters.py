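"""Structural restrictions, applied at the earliest stage where they are decidable.

Ring-count bounds (``-p``), planarity (``-P``) and badlist B9 depend only on
the simple skeleton and are enforced during stage 1; badlist B5 inspects bond
multiplicities and runs on completed molecules at stage 3.  Because adding an
edge can only create cycles (never destroy them) and every subgraph of a
planar graph is planar, a stage-1 violation of the 5-cycle *upper* bound, of
B9, or of planarity also dooms every descendant in the augmentation tree, so
those graphs are pruned outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "FilterConfig",
    "count_cycles",
    "is_planar",
    "passes_B9",
    "passes_B5",
    "stage1_prunable",
    "stage1_emit_ok",
]

#: Badlists described for this generator.  Other badlist numbers are rejected.
SUPPORTED_BADLISTS = frozenset({5, 9})


@dataclass(frozen=True)
class FilterConfig:
    """Optional structural restrictions.

    pentagon_bounds:
        ``(min, max)`` bounds on the number of 5-cycles (``-p MIN:MAX``).
    planar_only:
        keep only planar skeletons (``-P``).
    badlists:
        subset of :data:`SUPPORTED_BADLISTS` (``-B``).
    """

    pentagon_bounds: tuple[int, int] | None = None
    planar_only: bool = False
    badlists: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.pentagon_bounds is not None:
            lo, hi = self.pentagon_bounds
            if lo > hi or lo < 0:
                raise ValueError(f"bad 5-cycle bounds {self.pentagon_bounds}")
        unknown = set(self.badlists) - SUPPORTED_BADLISTS
        if unknown:
            raise ValueError(f"unknown badlist number(s): {sorted(unknown)}")
        object.__setattr__(self, "badlists", frozenset(self.badlists))

    def any_stage1(self) -> bool:
        return (
            self.pentagon_bounds is not None
            or self.planar_only
            or 9 in self.badlists
        )


def count_cycles(g, length: int) -> int:
    """Number of distinct simple cycles of exactly ``length`` vertices.

    A cycle is counted once as a set of vertices traversed: enumeration roots
    each cycle at its smallest vertex and fixes the traversal direction by
    requiring the second vertex to be smaller than the last.
    """
    if length < 3:
        raise ValueError("cycles have length >= 3")
    adj = g.adjacency
    n = g.n
    found: set[frozenset[int]] = set()

    def extend(start: int, path: list[int], on_path: set[int]) -> None:
        last = path[-1]
        if len(path) == length:
            if start in adj[last] and path[1] < last:
                found.add(frozenset(path))
            return
        for w in adj[last]:
            if w > start and w not in on_path:
                path.append(w)
                on_path.add(w)
                extend(start, path, on_path)
                on_path.discard(w)
                path.pop()

    for s in range(n):
        extend(s, [s], {s})
    return len(found)


def _cycles_upto_4(g) -> set[tuple[int, ...]]:
    """Simple cycles of length 3 or 4, deduplicated as sorted vertex tuples."""
    adj = g.adjacency
    out: set[tuple[int, ...]] = set()
    n = g.n
    for a in range(n):
        for b in adj[a]:
            if b <= a:
                continue
            for c in adj[b]:
                if c <= a or c == b:
                    continue
                if c in adj[a] and b < c:
                    out.add((a, b, c))
                # 4-cycles a-b-c-d-a rooted at a, direction fixed by b < d
                for d in adj[c]:
                    if d <= a or d == b:
                        continue
                    if d in adj[a] and b < d:
                        out.add(tuple(sorted((a, b, c, d))))
    return out


def is_planar(g) -> bool:
    """Planarity of the skeleton (linear-time criterion via networkx)."""
    G = nx.Graph()
    G.add_nodes_from(range(g.n))
    G.add_edges_from(g.edges)
    ok, _ = nx.check_planarity(G)
    return ok


def passes_B9(g) -> bool:
    """B9: no atom lies on more than one cycle of length 3 or 4.

    Cycles are distinct as vertex sets; one 3-cycle plus one 4-cycle through
    the same vertex already fails.
    """
    membership: dict[int, int] = {}
    for cyc in _cycles_upto_4(g):
        for v in cyc:
            membership[v] = membership.get(v, 0) + 1
            if membership[v] > 1:
                return False
    return True


def passes_B5(mol) -> bool:
    """B5: no atom has two double bonds and otherwise only hydrogen neighbours.

    An atom with exactly two incident double bonds fails when it has no other
    heavy neighbour — including the case where its remaining valence is zero
    (the "only hydrogens" condition holds vacuously), which is what rules out
    cumulated systems such as O=C=O.
    """
    n = mol.graph.n
    doubles = [0] * n
    heavy = [0] * n
    for (a, b), mult in zip(mol.graph.edges, mol.bonds):
        heavy[a] += 1
        heavy[b] += 1
        if mult == 2:
            doubles[a] += 1
            doubles[b] += 1
    for v in range(n):
        if doubles[v] == 2 and heavy[v] == 2:
            return False
    return True


def stage1_prunable(g, fc: FilterConfig) -> bool:
    """True if ``g`` and all of its edge-augmentation descendants fail."""
    if fc.pentagon_bounds is not None and count_cycles(g, 5) > fc.pentagon_bounds[1]:
        return True
    if 9 in fc.badlists and not passes_B9(g):
        return True
    if fc.planar_only and not is_planar(g):
        return True
    return False


def stage1_emit_ok(g, fc: FilterConfig) -> bool:
    """Emission-time stage-1 check (the non-monotone lower bounds)."""
    if fc.pentagon_bounds is not None and count_cycles(g, 5) < fc.pentagon_bounds[0]:
        return False
    return True
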