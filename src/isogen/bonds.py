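"""Stage 3: assign a bond multiplicity to every edge; hydrogens are implied.

This is the same orbit-selection problem as stage 2, transplanted to edges.
The acting group is the subgroup of Aut(G) that preserves the element list;
it again factors as (filtered N) x (edge minor subgroup), where the edge
minor subgroup permutes the edges joining a flower centre to same-element
leaves.  The N part is obtained purely by filtering stage 2's N — rejecting
automorphisms that move elements and converting the rest to their action on
the fixed edge order — never by a fresh automorphism computation.

Constraints: the incident multiplicity sum at each atom is at most its
valence, and the sum over atoms of (valence - incident bonds) equals the
hydrogen count, i.e. the multiplicities total the formula's bond count.
Within those bounds every completed multigraph admits exactly one hydrogen
placement, recorded per vertex in :class:`Molecule`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

from .formula import MolecularFormula
from .simplegen import SimpleGraph
from .symmetry import FlowerPartition, PermGroup, act_on_list, invert

__all__ = [
    "BondList",
    "Molecule",
    "edge_preserving_subgroup",
    "edge_flowers",
    "assign_multiplicities",
]

#: Multiplicity (1, 2 or 3) per edge, in the skeleton's fixed edge order.
BondList = tuple[int, ...]


@dataclass(frozen=True)
class Molecule:
    """A completed constitutional isomer (hydrogen-suppressed multigraph)."""

    graph: SimpleGraph
    elements: tuple[str, ...]
    bonds: BondList
    implicit_h: tuple[int, ...]

    @property
    def hydrogen_total(self) -> int:
        return sum(self.implicit_h)

    @property
    def bond_total(self) -> int:
        return sum(self.bonds)


def edge_preserving_subgroup(
    N: PermGroup, L: Sequence[str], g: SimpleGraph
) -> PermGroup:
    """Element-preserving members of N, as permutations of edge positions.

    Distinct vertex automorphisms inducing the same edge action collapse to
    one member; only the edge action matters for multiplicity lists.
    """
    idx = {e: i for i, e in enumerate(g.edges)}
    m = len(g.edges)
    members: set[tuple[int, ...]] = set()
    Lt = tuple(L)
    for gamma in N:
        if act_on_list(gamma, Lt) != Lt:
            continue
        eperm = [0] * m
        for i, (a, b) in enumerate(g.edges):
            x, y = gamma[a], gamma[b]
            eperm[idx[(x, y) if x < y else (y, x)]] = i
        # eperm built as inverse image; invert to one-line "maps i to"
        members.add(invert(tuple(eperm)))
    return PermGroup(members=frozenset(members), degree=m)


def edge_flowers(
    g: SimpleGraph, L: Sequence[str], fp: FlowerPartition
) -> FlowerPartition:
    """Minor structure on edge positions: same-element leaves of one flower.

    Each vertex-flower splits by assigned element; the edges from the common
    neighbour to one same-element leaf group form an edge-flower (singletons
    included).  Swapping two such edges is precisely a minor automorphism of
    the element-labelled graph, so multiplicities must be non-increasing along
    the edge order inside each edge-flower.
    """
    idx = {e: i for i, e in enumerate(g.edges)}
    out: list[tuple[int, ...]] = []
    for flower in fp.flowers:
        center = g.neighbors(flower[0])[0]
        groups: dict[str, list[int]] = {}
        for leaf in flower:
            e = (center, leaf) if center < leaf else (leaf, center)
            groups.setdefault(L[leaf], []).append(idx[e])
        for _, eidx in sorted(groups.items()):
            out.append(tuple(sorted(eidx)))
    return FlowerPartition(flowers=tuple(sorted(out)))


def assign_multiplicities(
    g: SimpleGraph,
    L: Sequence[str],
    f: MolecularFormula,
    edgeN: PermGroup,
    efp: FlowerPartition,
) -> Iterator[Molecule]:
    """Stream one completed molecule per orbit of bond assignments.

    The class-maximum convention mirrors stage 2 with multiplicity order
    1 < 2 < 3, so double and triple bonds pack toward low-numbered edges
    within an orbit.  The recursion walks the fixed edge order assigning the
    *extra* multiplicity (0..2 above the obligatory single bond) and prunes
    on the remaining bond budget and per-vertex residual valence.
    """
    edges = g.edges
    m = len(edges)
    n = g.n
    Lt = tuple(L)
    residual = [f.valences[Lt[v]] - g.degrees[v] for v in range(n)]
    if any(r < 0 for r in residual):
        return
    bond_total = (f.valence_sum - f.hydrogens) // 2
    extra_total = bond_total - m
    if extra_total < 0 or extra_total > 2 * m:
        return

    pred = [-1] * m
    for flower in efp.flowers:
        for a, b in zip(flower, flower[1:]):
            pred[b] = a

    n_inv = [invert(p) for p in edgeN if p != tuple(range(m))]
    x = [0] * m  # extra multiplicity per edge

    def n_maximal() -> bool:
        for ginv in n_inv:
            for w in range(m):
                img = x[ginv[w]]
                if img != x[w]:
                    if img > x[w]:
                        return False
                    break
        return True

    def rec(i: int, left: int) -> Iterator[Molecule]:
        if i == m:
            if left == 0 and n_maximal():
                bonds = tuple(xi + 1 for xi in x)
                implicit = tuple(residual)
                yield Molecule(
                    graph=g, elements=Lt, bonds=bonds, implicit_h=implicit
                )
            return
        if left > 2 * (m - i):
            return
        a, b = edges[i]
        cap = min(2, residual[a], residual[b], left)
        if pred[i] >= 0:
            cap = min(cap, x[pred[i]])
        for xi in range(cap, -1, -1):
            x[i] = xi
            residual[a] -= xi
            residual[b] -= xi
            yield from rec(i + 1, left - xi)
            residual[a] += xi
            residual[b] += xi
        x[i] = 0

    yield from rec(0, extra_total)
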