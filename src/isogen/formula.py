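"""Molecular formulas and the combinatorial parameters they imply.

A molecular formula such as ``C7H12O2S`` fixes everything stage 1 of the
generator needs: the number of heavy (non-hydrogen) atoms *n*, the hydrogen
count *h*, and — through the valence table — the total number of bonds
(counting multiplicity) of every constitutional isomer,

    bond_total = (sum_e counts[e] * valence[e] - h) / 2.

Since bond multiplicities are at most 3, a connected hydrogen-suppressed
skeleton must have between ``max(n - 1, ceil(bond_total / 3))`` and
``min(bond_total, n (n - 1) / 2)`` simple edges.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "DEFAULT_VALENCES",
    "FormulaError",
    "InfeasibleFormulaError",
    "MolecularFormula",
    "EdgeBudget",
    "parse_formula",
    "edge_budget",
]

#: Fixed single valence per element, per run.  Overridable via
#: ``parse_formula(..., valence_overrides=...)`` or the CLI ``-v`` flag.
DEFAULT_VALENCES: dict[str, int] = {
    "C": 4,
    "N": 3,
    "O": 2,
    "S": 2,
    "P": 3,
    "F": 1,
    "Cl": 1,
    "Br": 1,
    "I": 1,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed or unsupported molecular formula string."""


class InfeasibleFormulaError(Exception):
    """The formula admits no molecule (zero isomers).

    Raised when the hydrogen-adjusted valence sum is odd or negative, or when
    the implied bond total is too small for a connected skeleton.
    """


@dataclass(frozen=True)
class MolecularFormula:
    """Heavy-atom counts, hydrogen count and the valence table in force.

    Hydrogens are never graph vertices; they are implied by unused valence.
    """

    counts: Mapping[str, int]
    hydrogens: int
    valences: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_VALENCES))

    def __post_init__(self) -> None:
        for el in self.counts:
            if el not in self.valences:
                raise FormulaError(f"no valence known for element {el!r}")
        if self.n < 1:
            raise FormulaError("formula has no heavy atoms")

    @property
    def n(self) -> int:
        """Number of heavy atoms (vertices of the hydrogen-suppressed graph)."""
        return sum(self.counts.values())

    @property
    def valence_sum(self) -> int:
        return sum(c * self.valences[el] for el, c in self.counts.items())

    @property
    def max_valence(self) -> int:
        return max(self.valences[el] for el in self.counts)

    def element_order(self) -> tuple[str, ...]:
        """Elements present, in the fixed global (alphabetical) order.

        Every lexicographic comparison of element lists uses this order; any
        fixed total order would do, the choice only has to be consistent.
        """
        return tuple(sorted(self.counts))


@dataclass(frozen=True)
class EdgeBudget:
    """Edge-count range and degree bound for the stage-1 skeletons."""

    bond_total: int
    min_edges: int
    max_edges: int
    max_degree: int


def parse_formula(
    text: str, valence_overrides: Mapping[str, int] | None = None
) -> MolecularFormula:
    """Parse a Hill-style molecular formula string.

    Tokens are an element symbol (one upper-case letter, optionally one
    lower-case letter) followed by an optional count (default 1).  Hydrogen
    tokens may appear anywhere and accumulate into the hydrogen count;
    repeated heavy-element tokens accumulate too.

    Parameters
    ----------
    text:
        e.g. ``"C7H12O2S"`` or ``"CH4"``.
    valence_overrides:
        Optional ``{symbol: valence}`` map, merged over the defaults.
    """
    text = text.strip()
    if not text:
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    hydrogens = 0
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        sym, num = m.group(1), m.group(2)
        count = int(num) if num else 1
        if sym == "H":
            hydrogens += count
        elif count > 0:
            counts[sym] = counts.get(sym, 0) + count
        pos = m.end()

    valences = dict(DEFAULT_VALENCES)
    if valence_overrides:
        for el, v in valence_overrides.items():
            if v < 1:
                raise FormulaError(f"valence of {el!r} must be positive, got {v}")
            valences[el] = v
    for el in counts:
        if el not in valences:
            raise FormulaError(
                f"unknown element {el!r}; supply a valence override (e.g. {el}=4)"
            )
    if not counts:
        raise FormulaError(f"formula {text!r} has no heavy atoms")
    return MolecularFormula(counts=counts, hydrogens=hydrogens, valences=valences)


def edge_budget(f: MolecularFormula) -> EdgeBudget:
    """Derive the bond total and the simple-edge range for ``f``.

    Raises
    ------
    InfeasibleFormulaError
        If no molecule with this formula exists: odd or negative
        ``valence_sum - hydrogens``, a bond total below ``n - 1`` (skeleton
        cannot be connected), or an empty edge range.
    """
    n = f.n
    vh = f.valence_sum - f.hydrogens
    if vh < 0 or vh % 2:
        raise InfeasibleFormulaError(
            f"valence sum {f.valence_sum} minus hydrogens {f.hydrogens} "
            "must be non-negative and even"
        )
    bond_total = vh // 2
    if bond_total < n - 1:
        raise InfeasibleFormulaError(
            f"bond total {bond_total} cannot connect {n} heavy atoms"
        )
    min_edges = max(n - 1, math.ceil(bond_total / 3))
    max_edges = min(bond_total, n * (n - 1) // 2)
    if min_edges > max_edges:
        raise InfeasibleFormulaError(
            f"empty edge range [{min_edges}, {max_edges}]"
        )
    return EdgeBudget(
        bond_total=bond_total,
        min_edges=min_edges,
        max_edges=max_edges,
        max_degree=f.max_valence,
    )
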