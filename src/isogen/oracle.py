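"""Independent brute-force reference enumerator (test oracle).

Enumerates *all* labelled structures — every edge subset of the complete
graph, every element assignment, every multiplicity vector — keeps the
connected, valence-feasible, hydrogen-exact, filter-passing ones, and
deduplicates by an exhaustive-permutation canonical form.  Exponential on
purpose: it shares no code path with the staged generator, so agreement on
small formulas certifies the generator's completeness and isomorph-freeness.

Guarded to n <= 7 heavy atoms and h <= 12 hydrogens.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Iterator

from .filters import FilterConfig, count_cycles, is_planar, passes_B5, passes_B9
from .formula import InfeasibleFormulaError, MolecularFormula, edge_budget
from .simplegen import SimpleGraph
from .bonds import Molecule

__all__ = ["OracleResult", "brute_force_count"]

#: Canonical molecule encoding: elements in permuted order plus the sorted
#: (u, v, multiplicity) triples, minimized over all vertex permutations.
Encoding = tuple


@dataclass(frozen=True)
class OracleResult:
    count: int
    representatives: frozenset[Encoding]

    def __post_init__(self) -> None:
        assert self.count == len(self.representatives)


def _connected(n: int, adj: list[list[int]]) -> bool:
    seen = {0}
    stack = [0]
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == n


def _canonical_encoding(
    n: int, elements: tuple[str, ...], bonds: dict[tuple[int, int], int]
) -> Encoding:
    best = None
    for perm in permutations(range(n)):
        enc_elems = tuple(elements[v] for v in sorted(range(n), key=lambda v: perm[v]))
        enc_bonds = tuple(
            sorted(
                ((perm[a], perm[b]) if perm[a] < perm[b] else (perm[b], perm[a]))
                + (m,)
                for (a, b), m in bonds.items()
            )
        )
        enc = (enc_elems, enc_bonds)
        if best is None or enc < best:
            best = enc
    return best


def _element_assignments(n: int, counts: dict[str, int]) -> Iterator[tuple[str, ...]]:
    base: list[str] = []
    for el in sorted(counts):
        base.extend([el] * counts[el])
    seen: set[tuple[str, ...]] = set()
    for perm in permutations(base):
        if perm not in seen:
            seen.add(perm)
            yield perm


def _multiplicity_vectors(
    edges: list[tuple[int, int]],
    residual: list[int],
    extra_left: int,
) -> Iterator[tuple[int, ...]]:
    """All per-edge extra multiplicities (0..2) hitting the bond total."""
    m = len(edges)
    vec = [0] * m

    def rec(i: int, left: int) -> Iterator[tuple[int, ...]]:
        if i == m:
            if left == 0:
                yield tuple(vec)
            return
        if left > 2 * (m - i):
            return
        a, b = edges[i]
        for xi in range(min(2, residual[a], residual[b], left) + 1):
            vec[i] = xi
            residual[a] -= xi
            residual[b] -= xi
            yield from rec(i + 1, left - xi)
            residual[a] += xi
            residual[b] += xi
        vec[i] = 0

    yield from rec(0, extra_left)


def brute_force_count(
    f: MolecularFormula, filters: FilterConfig | None = None
) -> OracleResult:
    """Exact isomer count and canonical representatives by exhaustion."""
    n = f.n
    if n > 7 or f.hydrogens > 12:
        raise ValueError("oracle guard: needs n <= 7 heavy atoms and h <= 12")
    try:
        budget = edge_budget(f)
    except InfeasibleFormulaError:
        return OracleResult(count=0, representatives=frozenset())

    pairs = list(combinations(range(n), 2))
    maxval = f.max_valence
    reps: set[Encoding] = set()

    for mask in range(1 << len(pairs)):
        edges = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
        m = len(edges)
        if not (budget.min_edges <= m <= budget.max_edges):
            continue
        deg = [0] * n
        adj: list[list[int]] = [[] for _ in range(n)]
        for a, b in edges:
            deg[a] += 1
            deg[b] += 1
            adj[a].append(b)
            adj[b].append(a)
        if any(d > maxval for d in deg) or not _connected(n, adj):
            continue
        sg = SimpleGraph(n, edges)
        if filters is not None:
            if filters.pentagon_bounds is not None:
                c5 = count_cycles(sg, 5)
                lo, hi = filters.pentagon_bounds
                if not (lo <= c5 <= hi):
                    continue
            if filters.planar_only and not is_planar(sg):
                continue
            if 9 in filters.badlists and not passes_B9(sg):
                continue
        for elems in _element_assignments(n, dict(f.counts)):
            residual = [f.valences[elems[v]] - deg[v] for v in range(n)]
            if any(r < 0 for r in residual):
                continue
            extra = budget.bond_total - m
            for vec in _multiplicity_vectors(edges, residual, extra):
                bonds = {e: x + 1 for e, x in zip(edges, vec)}
                if filters is not None and 5 in filters.badlists:
                    mol = Molecule(
                        graph=sg,
                        elements=tuple(elems),
                        bonds=tuple(bonds[e] for e in sg.edges),
                        implicit_h=tuple(
                            f.valences[elems[v]]
                            - sum(mm for e, mm in bonds.items() if v in e)
                            for v in range(n)
                        ),
                    )
                    if not passes_B5(mol):
                        continue
                reps.add(_canonical_encoding(n, tuple(elems), bonds))
    return OracleResult(count=len(reps), representatives=frozenset(reps))
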