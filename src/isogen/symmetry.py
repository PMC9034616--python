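"""Automorphism groups, flowers, and the Aut(G) = N·M factorization.

The element-assignment stage needs one representative per orbit of label
lists under Aut(G).  Testing ``canon(L) = L`` directly is expensive when
Aut(G) is large, but for molecular skeletons most of the group order comes
from *minor* automorphisms — swaps of two degree-1 vertices (leaves) hanging
off the same neighbour.  A maximal set of leaves with a common neighbour is a
*flower*; the minor subgroup M generated by within-flower leaf swaps is a
direct product of symmetric groups, of order prod_F |F|!.

Colouring the vertices of each flower 1, 2, ... in order of vertex number
(and everything else 0) and taking N = the colour-preserving automorphisms
yields a complete, irredundant set of coset representatives: every
automorphism factors uniquely as nu·mu with nu in N and mu in M, so
|Aut(G)| = |N| · |M|.  A list L is then the lexicographic maximum of its
orbit iff (a) its labels are non-increasing by vertex number within each
flower (maximal w.r.t. M) and (b) gamma(L) <= L for every gamma in N.
N is small in practice, so (b) is cheap.

Vertices are numbered 0..n-1 throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import factorial
from typing import Iterable, Iterator, Sequence

import igraph as ig

__all__ = [
    "Permutation",
    "PermGroup",
    "FlowerPartition",
    "identity",
    "compose",
    "invert",
    "group_closure",
    "automorphism_group",
    "find_flowers",
    "flower_coloring",
    "compute_N",
    "act_on_list",
    "is_class_maximum",
    "nm_decompose",
]

logger = logging.getLogger(__name__)

#: One-line notation: p maps vertex v to p[v].
Permutation = tuple[int, ...]

#: Warn when an explicitly stored group grows beyond this many members.
GROUP_SIZE_WARNING = 10_000


def identity(n: int) -> Permutation:
    return tuple(range(n))


def compose(p: Permutation, q: Permutation) -> Permutation:
    """(p o q)(v) = p(q(v)) — apply ``q`` first."""
    return tuple(p[x] for x in q)


def invert(p: Permutation) -> Permutation:
    inv = [0] * len(p)
    for v, w in enumerate(p):
        inv[w] = v
    return tuple(inv)


@dataclass(frozen=True)
class PermGroup:
    """A finite permutation group stored as an explicit member set.

    Suitable for the small groups this generator meets (N is "very small most
    of the time"); not a general-purpose group implementation.
    """

    members: frozenset[Permutation]
    degree: int

    @property
    def order(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Permutation]:
        return iter(self.members)

    def __contains__(self, p: Permutation) -> bool:
        return tuple(p) in self.members

    @classmethod
    def from_generators(cls, gens: Iterable[Sequence[int]], degree: int) -> "PermGroup":
        return cls(members=frozenset(group_closure(gens, degree)), degree=degree)

    @classmethod
    def trivial(cls, degree: int) -> "PermGroup":
        return cls(members=frozenset({identity(degree)}), degree=degree)


def group_closure(gens: Iterable[Sequence[int]], degree: int) -> set[Permutation]:
    """All members of the group generated by ``gens`` (BFS closure)."""
    gens = [tuple(g) for g in gens]
    ident = identity(degree)
    members: set[Permutation] = {ident}
    frontier = [ident]
    warned = False
    while frontier:
        nxt: list[Permutation] = []
        for p in frontier:
            for g in gens:
                q = compose(g, p)
                if q not in members:
                    members.add(q)
                    nxt.append(q)
        frontier = nxt
        if not warned and len(members) > GROUP_SIZE_WARNING:
            logger.warning(
                "explicit permutation group exceeds %d members; "
                "closure may be slow", GROUP_SIZE_WARNING,
            )
            warned = True
    return members


def _as_igraph(g) -> ig.Graph:
    h = getattr(g, "igraph", None)
    if callable(h):
        return h()
    if isinstance(g, ig.Graph):
        return g
    return ig.Graph(g.n, list(g.edges))


def automorphism_group(g, vertex_colors: Sequence[int] | None = None) -> PermGroup:
    """Full (colour-preserving) automorphism group as an explicit set.

    ``g`` may be a :class:`~isogen.simplegen.SimpleGraph` or an igraph graph.
    The generators come from BLISS; the member set is their closure.
    """
    G = _as_igraph(g)
    colors = list(vertex_colors) if vertex_colors is not None else None
    gens = G.automorphism_group(color=colors)
    n = G.vcount()
    if not gens:
        return PermGroup.trivial(n)
    return PermGroup.from_generators(gens, n)


@dataclass(frozen=True)
class FlowerPartition:
    """Disjoint maximal same-neighbour leaf sets and the order of M.

    In the two-vertex graph both endpoints are leaves and each is the other's
    flower: two singleton flowers, no minor automorphism.
    """

    flowers: tuple[tuple[int, ...], ...]

    @property
    def minor_order(self) -> int:
        out = 1
        for f in self.flowers:
            out *= factorial(len(f))
        return out

    def member_map(self) -> dict[int, tuple[int, ...]]:
        return {v: f for f in self.flowers for v in f}


def find_flowers(g) -> FlowerPartition:
    """Group the degree-1 vertices of ``g`` by their unique neighbour."""
    deg = g.degrees
    by_center: dict[int, list[int]] = {}
    for v in range(g.n):
        if deg[v] == 1:
            (c,) = g.neighbors(v)
            by_center.setdefault(c, []).append(v)
    flowers = tuple(sorted(tuple(sorted(vs)) for vs in by_center.values()))
    return FlowerPartition(flowers=flowers)


def flower_coloring(g, fp: FlowerPartition) -> list[int]:
    """Colour the i-th lowest vertex of every flower i (1-based); others 0.

    Positions within different flowers share colours — N must preserve the
    *rank* of a leaf within its flower, not the flower itself.
    """
    colors = [0] * g.n
    for flower in fp.flowers:
        for i, v in enumerate(flower):
            colors[v] = i + 1
    return colors


def compute_N(g, fp: FlowerPartition | None = None) -> PermGroup:
    """The coset-representative subgroup N: colour-preserving automorphisms.

    Satisfies |Aut(g)| = N.order * fp.minor_order.
    """
    if fp is None:
        fp = find_flowers(g)
    return automorphism_group(g, flower_coloring(g, fp))


def act_on_list(p: Permutation, L: Sequence) -> tuple:
    """The image list: position ``p[v]`` of the result holds ``L[v]``."""
    if len(p) != len(L):
        raise ValueError(f"permutation degree {len(p)} != list length {len(L)}")
    out = [None] * len(L)
    for v, lab in zip(p, L):
        out[v] = lab
    return tuple(out)


def is_class_maximum(
    L: Sequence,
    N: PermGroup,
    fp: FlowerPartition,
    key=None,
) -> bool:
    """Is ``L`` the lexicographic maximum of its orbit under Aut(G) = N·M?

    Checks the two factor conditions: labels non-increasing by vertex number
    within each flower, and ``act_on_list(gamma, L) <= L`` for every gamma in
    N.  ``key`` maps a label to its rank in the fixed label order (default:
    natural ordering of the labels themselves).
    """
    if key is None:
        key = lambda x: x  # noqa: E731
    ranks = tuple(key(x) for x in L)
    for flower in fp.flowers:
        for a, b in zip(flower, flower[1:]):
            if ranks[a] < ranks[b]:
                return False
    for gamma in N:
        if act_on_list(gamma, ranks) > tuple(ranks):
            return False
    return True


def nm_decompose(
    gamma: Permutation, N: PermGroup, fp: FlowerPartition
) -> tuple[Permutation, Permutation]:
    """The unique factorization gamma = nu o mu with nu in N, mu in M.

    M membership is tested structurally: mu fixes every non-flower vertex and
    maps each flower onto itself.  Raises ``ValueError`` if the factorization
    does not exist or is not unique (which would falsify Aut = N·M).
    """
    member = {v: i for i, f in enumerate(fp.flowers) for v in f}
    found: list[tuple[Permutation, Permutation]] = []
    for nu in N:
        mu = compose(invert(nu), gamma)
        ok = True
        for v, w in enumerate(mu):
            if v in member:
                if member.get(w) != member[v]:
                    ok = False
                    break
            elif w != v:
                ok = False
                break
        if ok:
            found.append((nu, mu))
    if len(found) != 1:
        raise ValueError(
            f"expected exactly one N*M factorization, found {len(found)}"
        )
    return found[0]
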