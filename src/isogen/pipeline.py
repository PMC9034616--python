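"""The three-stage generation pipeline, end to end.

Everything streams: each stage-1 skeleton is processed to completion (element
lists, then bond lists) before the next one is generated, so memory use is
independent of the number of isomers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

from .bonds import (
    Molecule,
    assign_multiplicities,
    edge_flowers,
    edge_preserving_subgroup,
)
from .elements import assign_elements
from .filters import FilterConfig, passes_B5
from .formula import (
    InfeasibleFormulaError,
    MolecularFormula,
    edge_budget,
    parse_formula,
)
from .simplegen import SimpleGraph, _generate_raw
from .symmetry import PermGroup, compute_N, find_flowers, flower_coloring, group_closure

__all__ = [
    "generate_molecules",
    "count_isomers",
    "Stage1Survey",
    "stage1_survey",
]


def _as_formula(
    formula: str | MolecularFormula,
    valence_overrides: Mapping[str, int] | None = None,
) -> MolecularFormula:
    if isinstance(formula, MolecularFormula):
        return formula
    return parse_formula(formula, valence_overrides)


def generate_molecules(
    formula: str | MolecularFormula,
    filters: FilterConfig | None = None,
    valence_overrides: Mapping[str, int] | None = None,
    use_orbit_shortcut: bool = True,
) -> Iterator[Molecule]:
    """Stream every constitutional isomer of ``formula`` exactly once.

    ``filters`` applies the structural restrictions at their natural stages.
    An infeasible formula (odd valence sum, skeleton cannot connect, ...)
    yields an empty stream.
    """
    f = _as_formula(formula, valence_overrides)
    try:
        budget = edge_budget(f)
    except InfeasibleFormulaError:
        return
    check_b5 = filters is not None and 5 in filters.badlists
    for sg, G in _generate_raw(
        f.n, budget.min_edges, budget.max_edges, budget.max_degree, filters
    ):
        fp = find_flowers(sg)
        N = _colored_group(G, sg, fp)
        for L in assign_elements(sg, f, N, fp, use_orbit_shortcut=use_orbit_shortcut):
            edgeN = edge_preserving_subgroup(N, L, sg)
            efp = edge_flowers(sg, L, fp)
            for mol in assign_multiplicities(sg, L, f, edgeN, efp):
                if check_b5 and not passes_B5(mol):
                    continue
                yield mol


def _colored_group(G, sg: SimpleGraph, fp) -> PermGroup:
    """compute_N reusing the generator's live igraph handle."""
    gens = G.automorphism_group(color=flower_coloring(sg, fp))
    if not gens:
        return PermGroup.trivial(sg.n)
    return PermGroup.from_generators(gens, sg.n)


def count_isomers(
    formula: str | MolecularFormula,
    filters: FilterConfig | None = None,
    valence_overrides: Mapping[str, int] | None = None,
) -> int:
    """Number of constitutional isomers (exact, arbitrary precision)."""
    return sum(1 for _ in generate_molecules(formula, filters, valence_overrides))


@dataclass(frozen=True)
class Stage1Survey:
    """Statistics of the stage-1 sweep and its flower-coloured subgroups."""

    formula: str
    n: int
    min_edges: int
    max_edges: int
    max_degree: int
    graphs: int
    trivial_N: int
    max_N_order: int

    @property
    def trivial_N_percent(self) -> float:
        return 100.0 * self.trivial_N / self.graphs if self.graphs else 0.0


def stage1_survey(
    formula: str | MolecularFormula,
    valence_overrides: Mapping[str, int] | None = None,
    log_every: int | None = None,
) -> Stage1Survey:
    """Generate all stage-1 skeletons and survey their N subgroups.

    For each skeleton: find the flowers, colour them, and compute the order of
    the colour-preserving automorphism subgroup N.  Reports how often N is
    trivial and the largest |N| met.
    """
    import logging

    f = _as_formula(formula, valence_overrides)
    budget = edge_budget(f)
    graphs = trivial = 0
    max_order = 1
    logger = logging.getLogger(__name__)
    for sg, G in _generate_raw(
        f.n, budget.min_edges, budget.max_edges, budget.max_degree, None
    ):
        graphs += 1
        fp = find_flowers(sg)
        gens = G.automorphism_group(color=flower_coloring(sg, fp))
        if not gens:
            trivial += 1
        else:
            order = len(group_closure(gens, sg.n))
            if order == 1:
                trivial += 1
            elif order > max_order:
                max_order = order
        if log_every and graphs % log_every == 0:
            logger.info("stage-1 survey: %d graphs", graphs)
    return Stage1Survey(
        formula="".join(
            f"{el}{c if c > 1 else ''}" for el, c in sorted(f.counts.items())
        )
        + (f"H{f.hydrogens}" if f.hydrogens else ""),
        n=f.n,
        min_edges=budget.min_edges,
        max_edges=budget.max_edges,
        max_degree=budget.max_degree,
        graphs=graphs,
        trivial_N=trivial,
        max_N_order=max_order,
    )
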