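"""Stage 2: assign element symbols to vertices, one list per Aut(G)-orbit.

A labelling is represented as a list L with ``L[v]`` the element of vertex
``v``.  The emitted lists are exactly the lexicographic maxima of their
orbits, recognised via the N·M factorization: labels must be non-increasing
by vertex number within each flower (the M condition, enforced incrementally
during the recursion, as soon as a flower predecessor has been assigned) and
``gamma(L) <= L`` for every colour-preserving automorphism gamma in N (tested
once a list is complete — N is small).

The optional orbit shortcut adds the inequality ``element(v0) >= element(w)``
for the least vertex ``v0`` that N moves and the other members ``w`` of its
orbit: a necessary condition for N-maximality that prunes the recursion a
little earlier.  It never changes the emitted stream (the final N test is
still applied) and is off by default.
"""

from __future__ import annotations

from typing import Iterator, Sequence

from .formula import MolecularFormula
from .simplegen import SimpleGraph
from .symmetry import FlowerPartition, PermGroup, invert

__all__ = ["ElementList", "assign_elements"]

#: An element assignment: position v holds the element symbol of vertex v.
ElementList = tuple[str, ...]


def _flower_predecessors(fp: FlowerPartition, n: int) -> list[int]:
    """pred[v] = previous vertex of v's flower (by number), else -1."""
    pred = [-1] * n
    for flower in fp.flowers:
        for a, b in zip(flower, flower[1:]):
            pred[b] = a
    return pred


def _orbit_bounds(N: PermGroup, n: int) -> list[int]:
    """bound[w] = v0 for members w of the first non-trivial N-orbit, else -1.

    Only the orbit of the least vertex v0 moved by N yields a sound
    inequality ``element(v0) >= element(w)``: every position before v0 is
    fixed by all of N, so an automorphism carrying w to v0 changes nothing
    earlier and a larger element at w would contradict N-maximality.  The
    same bound applied to later orbits can prune valid representatives
    (the automorphism may already lose at an earlier position).
    """
    bound = [-1] * n
    for v in range(n):
        if any(g[v] != v for g in N):
            orbit = {v}
            stack = [v]
            while stack:
                a = stack.pop()
                for g in N:
                    x = g[a]
                    if x not in orbit:
                        orbit.add(x)
                        stack.append(x)
            for w in orbit:
                if w != v:
                    bound[w] = v
            break
    return bound


def assign_elements(
    g: SimpleGraph,
    f: MolecularFormula,
    N: PermGroup,
    fp: FlowerPartition,
    use_orbit_shortcut: bool = False,
) -> Iterator[ElementList]:
    """Stream the class-maximum element lists for skeleton ``g``.

    Every emitted list has the exact element counts of ``f`` and satisfies
    ``valence >= degree`` at each vertex; exactly one member of each orbit
    under Aut(g) is emitted.  The stream may be empty (e.g. a degree-4 vertex
    but no tetravalent element left).
    """
    n = g.n
    symbols = f.element_order()  # ascending fixed order; index = rank
    k = len(symbols)
    avail = [f.counts[s] for s in symbols]
    valences = [f.valences[s] for s in symbols]
    deg = g.degrees
    pred = _flower_predecessors(fp, n)
    # inverse permutations once: act(gamma, L)[w] = L[gamma^{-1}(w)]
    n_inv = [invert(p) for p in N if p != tuple(range(n))]
    obound = _orbit_bounds(N, n) if use_orbit_shortcut and n_inv else None

    L = [-1] * n

    def n_maximal() -> bool:
        for ginv in n_inv:
            for w in range(n):
                img = L[ginv[w]]
                if img != L[w]:
                    if img > L[w]:
                        return False
                    break
        return True

    def rec(v: int) -> Iterator[ElementList]:
        if v == n:
            if n_maximal():
                yield tuple(symbols[c] for c in L)
            return
        hi = k - 1
        if pred[v] >= 0 and L[pred[v]] < hi:
            hi = L[pred[v]]
        if obound is not None and obound[v] >= 0 and L[obound[v]] < hi:
            hi = L[obound[v]]
        d = deg[v]
        for c in range(hi, -1, -1):
            if avail[c] and valences[c] >= d:
                avail[c] -= 1
                L[v] = c
                yield from rec(v + 1)
                avail[c] += 1
        L[v] = -1

    if sum(avail) != n:
        raise ValueError("element counts do not match vertex count")
    yield from rec(0)
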