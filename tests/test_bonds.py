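"""Stage 3: bond multiplicities, one assignment per orbit; hydrogen bookkeeping."""

from itertools import product

import pytest

from isogen.bonds import (
    assign_multiplicities,
    edge_flowers,
    edge_preserving_subgroup,
)
from isogen.formula import MolecularFormula, edge_budget, parse_formula
from isogen.pipeline import generate_molecules
from isogen.simplegen import SimpleGraph
from isogen.symmetry import act_on_list, compute_N, find_flowers

from conftest import brute_automorphisms


def _stage3(g, L, f):
    fp = find_flowers(g)
    N = compute_N(g, fp)
    edgeN = edge_preserving_subgroup(N, L, g)
    efp = edge_flowers(g, L, fp)
    return list(assign_multiplicities(g, L, f, edgeN, efp)), edgeN


def test_furan_skeleton_bond_assignment_orbits(c5):
    """O on a 5-cycle, two extra bond units on the C-C edges: the reflection
    through the oxygen pairs up assignments, leaving 4 orbits (the furan
    double-double pattern, the adjacent-doubles pair, and two triples)."""
    f = MolecularFormula(counts={"C": 4, "O": 1}, hydrogens=4)
    L = ("O", "C", "C", "C", "C")  # class-maximum placement on the cycle
    mols, edgeN = _stage3(c5, L, f)
    assert edgeN.order == 2  # identity and the reflection through the oxygen
    assert len(mols) == 4
    # the furan Kekulé pattern is among them: doubles on the two C-C edges
    # not incident to the oxygen's neighbours' shared side
    assert {m.bonds for m in mols} == _brute_bond_orbit_reps(c5, L, f)


def test_methane_single_molecule_with_four_hydrogens():
    g = SimpleGraph(1, ())
    f = parse_formula("CH4")
    mols, _ = _stage3(g, ("C",), f)
    assert len(mols) == 1
    assert mols[0].implicit_h == (4,)
    assert mols[0].bonds == ()


def test_edge_group_rejects_element_moving_automorphisms(c5):
    fp = find_flowers(c5)
    N = compute_N(c5, fp)
    assert N.order == 10
    # O at position 0: only identity and the reflection fixing 0 survive
    edgeN = edge_preserving_subgroup(N, ("O", "C", "C", "C", "C"), c5)
    assert edgeN.order == 2
    # all carbons: every automorphism survives (as an edge action)
    edgeN_allc = edge_preserving_subgroup(N, ("C",) * 5, c5)
    assert edgeN_allc.order == 10


def test_edge_flowers_split_by_element():
    # all four neighbours of centre 3 are leaves: one flower {0,1,2,4}
    g = SimpleGraph(5, [(0, 3), (1, 3), (2, 3), (3, 4)])
    fp = find_flowers(g)
    assert fp.flowers == ((0, 1, 2, 4),)
    ef_same = edge_flowers(g, ("C", "C", "C", "C", "O"), fp)
    assert (0, 1, 2) in ef_same.flowers  # the three C edges 0-3, 1-3, 2-3
    ef_mixed = edge_flowers(g, ("O", "C", "C", "C", "C"), fp)
    assert sorted(len(f) for f in ef_mixed.flowers) == [1, 3]
    # no leaves -> no edge flowers
    c5 = SimpleGraph(5, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)])
    assert edge_flowers(c5, ("C",) * 5, find_flowers(c5)).flowers == ()


def _brute_bond_orbit_reps(g, L, f):
    """Independent route: all multiplicity vectors satisfying valence and
    hydrogen constraints, reduced to maxima under the full element-preserving
    automorphism group computed by exhaustive search."""
    bond_total = edge_budget(f).bond_total
    val = {el: f.valences[el] for el in set(L)}
    aut = [p for p in brute_automorphisms(g) if act_on_list(p, L) == tuple(L)]
    eidx = {e: i for i, e in enumerate(g.edges)}
    eperms = []
    for p in aut:
        im = [0] * len(g.edges)
        for i, (a, b) in enumerate(g.edges):
            x, y = p[a], p[b]
            im[i] = eidx[(x, y) if x < y else (y, x)]
        eperms.append(im)
    reps = set()
    for vec in product((1, 2, 3), repeat=len(g.edges)):
        if sum(vec) != bond_total:
            continue
        sums = [0] * g.n
        for (a, b), m in zip(g.edges, vec):
            sums[a] += m
            sums[b] += m
        if any(sums[v] > val[L[v]] for v in range(g.n)):
            continue
        best = vec
        for ep in eperms:
            img = tuple(vec[i] for i in _invert(ep))
            if img > best:
                best = img
        reps.add(best)
    return reps


def _invert(p):
    inv = [0] * len(p)
    for i, j in enumerate(p):
        inv[j] = i
    return inv


CASES = [
    (SimpleGraph(5, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)]),
     ("O", "C", "C", "C", "C"), "C4H4O"),
    (SimpleGraph(5, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)]),
     ("C", "C", "C", "C", "C"), "C5H6"),
    (SimpleGraph(5, [(0, 3), (1, 3), (2, 3), (3, 4)]),
     ("O", "C", "C", "C", "C"), "C4H6O"),
    (SimpleGraph(4, [(0, 1), (1, 2), (2, 3)]), ("N", "C", "C", "N"), "C2H4N2"),
    (SimpleGraph(4, [(0, 3), (1, 3), (2, 3)]), ("C", "C", "C", "C"), "C4H6"),
]


@pytest.mark.parametrize("g,L,formula", CASES, ids=[c[2] for c in CASES])
def test_emitted_bondlists_are_exactly_the_brute_force_orbit_reps(g, L, formula):
    f = parse_formula(formula)
    mols, _ = _stage3(g, L, f)
    got = {m.bonds for m in mols}
    assert got == _brute_bond_orbit_reps(g, L, f)
    assert len(mols) == len(got)


@pytest.mark.parametrize("formula", ["C4H4O", "C3H4O2", "C5H8", "C2H3N", "C6H6"])
def test_conservation_laws_hold_for_every_generated_molecule(formula):
    f = parse_formula(formula)
    bond_total = edge_budget(f).bond_total
    count = 0
    for mol in generate_molecules(f):
        assert mol.bond_total == bond_total
        assert mol.hydrogen_total == f.hydrogens
        assert all(h >= 0 for h in mol.implicit_h)
        # implicit_h is exactly the unused valence at each vertex
        sums = [0] * mol.graph.n
        for (a, b), m in zip(mol.graph.edges, mol.bonds):
            sums[a] += m
            sums[b] += m
        for v in range(mol.graph.n):
            assert sums[v] + mol.implicit_h[v] == f.valences[mol.elements[v]]
        count += 1
    assert count > 0
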