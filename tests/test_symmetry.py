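"""Automorphism groups, flowers and the N*M factorization."""

import pytest

from isogen.formula import EdgeBudget
from isogen.simplegen import SimpleGraph, generate_simple_graphs
from isogen.symmetry import (
    FlowerPartition,
    act_on_list,
    automorphism_group,
    compose,
    compute_N,
    find_flowers,
    flower_coloring,
    invert,
    is_class_maximum,
    nm_decompose,
)

from conftest import brute_automorphisms, brute_canon_list


class TestAutomorphismGroup:
    def test_five_cycle_has_order_ten(self, c5):
        assert automorphism_group(c5).order == 10

    def test_single_vertex_trivial(self):
        assert automorphism_group(SimpleGraph(1, ())).order == 1

    def test_furan_coloring_leaves_only_the_reflection(self, c5):
        # one vertex (the oxygen position) coloured apart from the carbons
        colors = [1, 0, 0, 0, 0]
        grp = automorphism_group(c5, colors)
        assert grp.order == 2
        assert all(p[0] == 0 for p in grp)

    @pytest.mark.parametrize(
        "edges,n",
        [
            ([(0, 1), (1, 2), (2, 3), (3, 0), (0, 2), (1, 3)], 4),  # K4
            ([(0, 1), (1, 2), (2, 3)], 4),  # path
            ([(0, 3), (1, 3), (2, 3), (3, 4), (4, 5)], 6),
        ],
    )
    def test_matches_exhaustive_bijection_search(self, edges, n):
        g = SimpleGraph(n, edges)
        assert set(automorphism_group(g)) == set(brute_automorphisms(g))


class TestFlowers:
    def test_star_is_one_flower(self, star3):
        fp = find_flowers(star3)
        assert fp.flowers == ((0, 1, 2),)
        assert fp.minor_order == 6

    def test_cycle_has_no_flowers(self, c5):
        fp = find_flowers(c5)
        assert fp.flowers == ()
        assert fp.minor_order == 1

    def test_flower_sizes_3_2_2_give_minor_order_24(self):
        # spider: leaves {0,1,2} on centre 3, {5,6} on 4, {8,9} on 7
        g = SimpleGraph(
            10,
            [(0, 3), (1, 3), (2, 3), (3, 4), (4, 5), (4, 6), (4, 7), (7, 8), (7, 9)],
        )
        fp = find_flowers(g)
        assert sorted(len(f) for f in fp.flowers) == [2, 2, 3]
        assert fp.minor_order == 24

    def test_two_vertex_graph_gives_singleton_flowers(self):
        fp = find_flowers(SimpleGraph(2, [(0, 1)]))
        assert fp.flowers == ((0,), (1,))
        assert fp.minor_order == 1

    def test_coloring_ranks_within_each_flower(self):
        g = SimpleGraph(
            7, [(0, 2), (1, 2), (2, 3), (3, 4), (4, 5), (4, 6)]
        )  # flowers {0,1} (centre 2) and {5,6} (centre 4)
        fp = find_flowers(g)
        colors = flower_coloring(g, fp)
        assert colors == [1, 2, 0, 0, 0, 1, 2]

    def test_coloring_all_reserved_without_flowers(self, c5):
        assert flower_coloring(c5, find_flowers(c5)) == [0] * 5


class TestFactorization:
    @pytest.mark.parametrize(
        "edges,n",
        [
            ([(0, 1), (1, 2)], 3),  # path: Aut 2 = N 1 * 2!
            ([(0, 3), (1, 3), (2, 3)], 4),  # star: Aut 6 = N 1 * 3!
            ([(0, 2), (1, 2), (2, 3), (3, 4), (4, 5), (4, 6)], 7),
            ([(0, 4), (1, 4), (2, 5), (3, 5), (4, 5)], 6),  # H-shape
        ],
    )
    def test_order_factorizes(self, edges, n):
        g = SimpleGraph(n, edges)
        fp = find_flowers(g)
        N = compute_N(g, fp)
        assert len(brute_automorphisms(g)) == N.order * fp.minor_order

    def test_order_factorizes_on_all_stage1_graphs_up_to_seven(self):
        budget = EdgeBudget(bond_total=9, min_edges=6, max_edges=8, max_degree=4)
        count = 0
        for g in generate_simple_graphs(budget, 7):
            fp = find_flowers(g)
            N = compute_N(g, fp)
            assert len(brute_automorphisms(g)) == N.order * fp.minor_order
            count += 1
        assert count > 50

    def test_every_automorphism_decomposes_uniquely(self):
        g = SimpleGraph(
            7, [(0, 2), (1, 2), (2, 3), (3, 4), (4, 5), (4, 6)]
        )
        fp = find_flowers(g)
        N = compute_N(g, fp)
        for gamma in brute_automorphisms(g):
            nu, mu = nm_decompose(gamma, N, fp)  # raises unless unique
            assert compose(nu, mu) == gamma
            assert nu in N


class TestListAction:
    def test_displayed_example(self):
        # gamma = (1 2 3)(5 6) in 1-based cycle notation
        gamma = (1, 2, 0, 3, 5, 4, 6, 7, 8, 9)
        L = ("C", "C", "O", "S", "O", "C", "C", "C", "C", "C")
        assert act_on_list(gamma, L) == (
            "O", "C", "C", "S", "C", "O", "C", "C", "C", "C",
        )

    def test_identity_and_inverse_laws(self):
        L = ("C", "O", "N", "C", "S")
        ident = tuple(range(5))
        assert act_on_list(ident, L) == L
        p = (2, 0, 4, 1, 3)
        assert act_on_list(invert(p), act_on_list(p, L)) == L

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            act_on_list((0, 1), ("C",))


def _all_labelings(n, symbols):
    from itertools import product

    return product(symbols, repeat=n)


class TestClassMaximum:
    def test_trivial_group_no_flowers_accepts_everything(self, c5):
        from isogen.symmetry import PermGroup

        N = PermGroup.trivial(5)
        fp = FlowerPartition(flowers=())
        assert is_class_maximum(("C", "O", "C", "O", "C"), N, fp)

    @pytest.mark.parametrize(
        "edges,n",
        [
            ([(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)], 5),
            ([(0, 3), (1, 3), (2, 3), (3, 4)], 5),
            ([(0, 2), (1, 2), (2, 3), (3, 4), (4, 5), (4, 6)], 7),
            ([(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)], 4),
        ],
    )
    def test_agrees_with_brute_force_canon_exhaustively(self, edges, n):
        """The factorized test equals canon(L)=L over the full Aut group."""
        g = SimpleGraph(n, edges)
        fp = find_flowers(g)
        N = compute_N(g, fp)
        aut = brute_automorphisms(g)
        accepted = 0
        for L in _all_labelings(n, ("C", "N", "O")):
            fast = is_class_maximum(L, N, fp)
            slow = brute_canon_list(L, aut) == tuple(L)
            assert fast == slow
            accepted += fast
        # exactly one representative per orbit
        orbits = {
            tuple(brute_canon_list(L, aut))
            for L in _all_labelings(n, ("C", "N", "O"))
        }
        assert accepted == len(orbits)
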