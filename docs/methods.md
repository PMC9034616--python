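# Methods

## Problem and model

isogen enumerates the constitutional isomers of a molecular formula: all
connected multigraphs on the heavy atoms, with one element symbol per vertex
matching the formula's counts, edge multiplicities in {1, 2, 3}, the incident
multiplicity sum at each atom bounded by that element's valence, and the total
unused valence equal to the hydrogen count. Hydrogens are never vertices; once
the heavy-atom multigraph is fixed they attach in exactly one way. Two isomers
are the same iff an isomorphism matches both elements and multiplicities.
Stereochemistry, charges, radicals, isotopes and aromatic perception are out of
scope; in particular graph-theoretically distinct Kekulé forms of one aromatic
ring count as distinct molecules (no Hückel test), which is why the benzene
formula C6H6 counts 217.

Each element has one fixed valence for the whole run (defaults: C 4, N 3, O 2,
S 2, P 3, F/Cl/Br/I 1). This is a real modelling restriction: multivalent
sulfur/phosphorus chemistry needs an explicit override (`-v S=6`), and counts
for S/P-containing formulas depend on that choice.

## Stage 1 — skeletons by canonical augmentation

The hydrogen-suppressed skeleton of any isomer is a connected simple graph
whose edge count m satisfies `max(n−1, ⌈B/3⌉) ≤ m ≤ min(B, n(n−1)/2)`, with
`B = (Σ valences − #H)/2` the bond total, and whose degrees respect the largest
valence present (per-element caps apply only after elements are placed).

One labelled representative per isomorphism class is produced by canonical
augmentation: trees grow by attaching a leaf, graphs with cycles grow by
inserting an edge; a child is accepted iff the element just added belongs to
the orbit of a canonically chosen deletable element (a leaf, or a non-bridge
edge — deletion must keep the graph connected). The
canonical choice maximizes a cheap isomorphism-invariant score first (the
neighbour degree for leaves, the sorted endpoint-degree pair for edges) and
breaks ties by BLISS canonical labels; orbit membership is decided with BLISS
automorphism generators only when the direct label comparison is inconclusive.
Candidate augmentations are taken up to Aut(parent)-orbits, which together
with the parent rule yields exactly one accepted construction per child class
— no storage, no cross-comparison, pure streaming. Accepted children are
relabelled to canonical form, making the emitted representatives deterministic
and order-independent.

The degree cap and the monotone filters (5-cycle upper bound, planarity, B9)
prune entire augmentation subtrees: all three properties can only get worse
when an edge is added, and a parent is always a subgraph of its descendants.

## Stage 2 — elements via Aut(G) = N·M

Orbit selection on label lists uses the flower factorization. A *flower* is a
maximal set of leaves with a common neighbour; the minor subgroup M generated
by within-flower leaf swaps has order Π|F|!. Colouring each flower's vertices
1, 2, ... in vertex-number order (non-flower vertices 0) and letting N be the
colour-preserving automorphisms gives Aut(G) = N·M with unique factorization,
so a list is the lexicographic maximum of its orbit iff it is non-increasing
inside every flower and undominated under the (small) group N. The flower
inequalities are enforced during the recursion the moment a flower
predecessor is assigned; the N test runs on completed lists. Element order
for all comparisons is the fixed alphabetical order of symbols (any fixed
total order works; a property test checks the counts are order-invariant).

The only degenerate flower case is the two-vertex molecule, where each vertex
is the other's flower: two singletons, no minor automorphism.

An optional shortcut adds `element(v0) ≥ element(w)` for the least vertex v0
moved by N and the other members w of its orbit. Restricting it to that first
orbit matters: every earlier position is fixed by all of N, so the exchange
argument is airtight there, whereas the same inequality imposed on later
orbits can prune valid representatives (an automorphism moving a later orbit
may already lose at an earlier position). The shortcut never changes the
output — the final N test stands — and is enabled in the pipeline, off by
default in the low-level API.

## Stage 3 — multiplicities

The same machinery acts on edge positions. The acting group is the
element-preserving subgroup: the stage-2 N filtered to list stabilizers and
converted to edge permutations (never recomputed from scratch), times the
edge minor subgroup given by same-element leaf edges within one flower. The
recursion walks the fixed edge order (sorted vertex pairs, frozen at stage 1)
assigning the extra multiplicity 0–2 per edge, largest first, pruning on the
remaining bond budget (≤ 2 × remaining edges) and per-vertex residual
valence; edge-flower positions must be non-increasing, and completed lists
must be undominated under the filtered N. Per-vertex hydrogen counts are the
residual valences left at the end.

## Filters

* `-p MIN:MAX` bounds the number of 5-cycles, counted as distinct vertex sets
  of simple cycles (chord-induced alternative cycles on the same vertex set
  are not double-counted). Enforced in stage 1: the upper bound prunes, the
  lower bound gates emission.
* `-P` keeps planar skeletons only (networkx's linear-time test).
* `-B9` rejects skeletons where any vertex lies on two distinct cycles of
  length 3 or 4 (vertex-set semantics again — an SSSR reading would differ on
  pathological fused systems; this is a documented interpretation choice).
* `-B5` rejects molecules containing an atom with exactly two double bonds
  and no further heavy neighbour — the "nothing else but hydrogens" clause is
  read as vacuously true for atoms with no remaining valence, so cumulated
  systems like O=C=O are caught. Runs at stage 3, the first point where bond
  orders exist.

Early (stage-1) and late (whole-molecule) filtering are equivalent; a test
checks the commutation explicitly on a small formula.

## Output

SMILES comes from a per-skeleton template — a DFS spanning-tree walk with
ring-closure digits and slots for atoms and bond orders — so each molecule
costs only slot filling. Atom tokens use bare organic-subset symbols when the
reader's default-valence hydrogen inference reproduces the generator's count,
bracket atoms with explicit H counts otherwise. SDfile output is V2000 with
zero coordinates ("0D": constitution carries no geometry). Counts use Python
integers throughout (formula spaces beyond 2^31 are routine in this domain).

## Numerical / implementation choices

* Canonical labelling and automorphism generators come from igraph's BLISS;
  groups are materialized as explicit member sets only where they are known
  to be small (N; a guard logs a warning past 10,000 members). The stage-1
  parent rule never materializes a group — it uses generators and orbits.
* All sequences are compared lexicographically with maxima as
  representatives; choosing minima would be equally valid but the convention
  must be (and is) consistent across stages.
* Tie-breaks inside the augmentation accept test happen in a fixed order
  (edge-list position), making generation bit-for-bit reproducible; there is
  no randomness anywhere in the package.
* Recursion depth is bounded by n + the cycle rank (≤ ~40 for anything
  tractable), well inside Python limits.

## Testing strategy and its limits

Correctness rests on dual routes: a brute-force oracle enumerates *all*
labelled structures (edge subsets × labelings × multiplicity vectors,
deduplicated by exhaustive-permutation canonical forms, guard n ≤ 7) and must
agree with the pipeline on every small formula, with and without each filter;
group-theoretic claims (the N·M factorization, unique decomposition, the
class-maximum criterion vs. explicit canon computation) are checked
exhaustively on small graphs against automorphisms found by trying all n!
bijections; SMILES/SDF round-trips are validated with RDKit, an independent
toolkit. Desk-scale characteristic quantities of the method — the C7H12O2S
edge range 9–11, the furan-skeleton group orders 10 and 2, the 534,493
Lysopine skeletons with N trivial for 58% of them and never larger than 72 —
are recomputed in the acceptance tests; billion-molecule stage-2/3 totals for
formulas of that size are beyond a pure-Python desk run and are certified
indirectly through the oracle equivalences and conservation invariants.

Small-n exhaustiveness is the main limitation of the evidence: the oracle
window (≤ 7 heavy atoms) exercises every code path — flowers, non-trivial N,
cycles, filters — but cannot probe scale-dependent behaviour directly; the
Lysopine stage-1 sweep (n = 15, half a million classes) is the large-scale
anchor.
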