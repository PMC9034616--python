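"""SMILES and SDfile output.

SMILES strings are produced from a per-skeleton *template*: a spanning-tree
walk of the simple graph, computed once per stage-1 graph, with placeholder
slots for atom symbols and bond orders.  Emitting one of the (typically very
many) molecules that share a skeleton then only fills the slots — no graph
traversal per molecule.

Output follows the raw generation labelling (no canonical SMILES); double
and triple bonds are written ``=`` and ``#``; hydrogens stay implicit where
SMILES default valences reproduce them and are written as bracket-atom
H-counts otherwise.  SDfile output is minimal V2000 with zero coordinates
(the generator knows constitution only, no geometry).
"""

from __future__ import annotations

from dataclasses import dataclass

from .bonds import Molecule
from .simplegen import SimpleGraph

__all__ = ["SmilesTemplate", "build_smiles_template", "write_smiles", "write_sdf"]

#: Default valence lists of the SMILES organic subset, used by readers to
#: infer implicit hydrogens on bare atom symbols.
_ORGANIC_VALENCES: dict[str, tuple[int, ...]] = {
    "B": (3,),
    "C": (4,),
    "N": (3, 5),
    "O": (2,),
    "P": (3, 5),
    "S": (2, 4, 6),
    "F": (1,),
    "Cl": (1,),
    "Br": (1,),
    "I": (1,),
}

_BOND_CHAR = {1: "", 2: "=", 3: "#"}


@dataclass(frozen=True)
class SmilesTemplate:
    """Token stream of a spanning-tree walk with ring closures.

    Tokens: ``("atom", v)``, ``("bond", edge_index)``, ``("ring", edge_index,
    digit)``, ``"("`` and ``")"``.  Every edge of the skeleton appears exactly
    once, as a tree bond or as a ring closure; ring-closure digits are
    assigned in discovery order.
    """

    n: int
    tokens: tuple


def build_smiles_template(g: SimpleGraph) -> SmilesTemplate:
    """Deterministic template: depth-first from vertex 0, neighbours in order."""
    eidx = {e: i for i, e in enumerate(g.edges)}
    tokens: list = []
    visited = [False] * g.n
    used_edges: set[int] = set()
    next_digit = [1]
    # ring closures discovered at the far end must emit a digit at both atoms;
    # collect per-vertex closure tokens and splice after each atom token.
    closures: dict[int, list[tuple[int, int]]] = {v: [] for v in range(g.n)}

    order: list[int] = []

    def walk(v: int) -> list:
        visited[v] = True
        order.append(v)
        out: list = [("atom", v)]
        branches: list[list] = []
        for w in g.neighbors(v):
            e = (v, w) if v < w else (w, v)
            i = eidx[e]
            if i in used_edges:
                continue
            if visited[w]:
                used_edges.add(i)
                d = next_digit[0]
                next_digit[0] += 1
                closures[v].append((i, d))
                closures[w].append((i, d))
            else:
                used_edges.add(i)
                branches.append([("bond", i)] + walk(w))
        for b in branches[:-1]:
            out.append("(")
            out.extend(b)
            out.append(")")
        if branches:
            out.extend(branches[-1])
        return out

    raw = walk(0)
    if len(order) != g.n:
        raise ValueError("skeleton is not connected")
    # splice ring-closure tokens directly after their atom token
    for tok in raw:
        tokens.append(tok)
        if isinstance(tok, tuple) and tok[0] == "atom":
            for i, d in closures[tok[1]]:
                tokens.append(("ring", i, d))
    return SmilesTemplate(n=g.n, tokens=tuple(tokens))


def _atom_text(symbol: str, bond_sum: int, n_h: int) -> str:
    dflt = _ORGANIC_VALENCES.get(symbol)
    if dflt is not None:
        inferred = next((v for v in dflt if v >= bond_sum), None)
        if inferred is not None and inferred - bond_sum == n_h:
            return symbol
    if n_h == 0:
        return f"[{symbol}]"
    if n_h == 1:
        return f"[{symbol}H]"
    return f"[{symbol}H{n_h}]"


def _ring_digit(d: int) -> str:
    return str(d) if d <= 9 else f"%{d}"


def write_smiles(m: Molecule, t: SmilesTemplate | None = None) -> str:
    """One SMILES line for ``m`` (template built on the fly if not given)."""
    if t is None:
        t = build_smiles_template(m.graph)
    bond_sums = [0] * m.graph.n
    for (a, b), mult in zip(m.graph.edges, m.bonds):
        bond_sums[a] += mult
        bond_sums[b] += mult
    parts: list[str] = []
    for tok in t.tokens:
        if tok == "(" or tok == ")":
            parts.append(tok)
        elif tok[0] == "atom":
            v = tok[1]
            parts.append(_atom_text(m.elements[v], bond_sums[v], m.implicit_h[v]))
        elif tok[0] == "bond":
            parts.append(_BOND_CHAR[m.bonds[tok[1]]])
        else:  # ring closure: bond symbol on both sides, digit after
            parts.append(_BOND_CHAR[m.bonds[tok[1]]] + _ring_digit(tok[2]))
    return "".join(parts)


def write_sdf(m: Molecule, index: int = 1) -> str:
    """A V2000 molfile block (zero coordinates) ending in ``$$$$``."""
    n, nb = m.graph.n, len(m.graph.edges)
    if n > 999 or nb > 999:
        raise ValueError("V2000 molfiles support at most 999 atoms/bonds")
    lines = [
        f"isogen-{index}",
        "  isogen          0D",
        "",
        f"{n:3d}{nb:3d}  0  0  0  0  0  0  0  0999 V2000",
    ]
    for v in range(n):
        lines.append(
            f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {m.elements[v]:<3s}"
            " 0  0  0  0  0  0  0  0  0  0  0  0"
        )
    for (a, b), mult in zip(m.graph.edges, m.bonds):
        lines.append(f"{a + 1:3d}{b + 1:3d}{mult:3d}  0")
    lines.append("M  END")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"
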