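# isogen

Exhaustive, duplicate-free generation of the **constitutional isomers** of a
molecular formula: every molecule with the given atom counts, produced exactly
once, as a hydrogen-suppressed multigraph with implicit hydrogens.

Structure generators of this kind are the engine behind computer-assisted
structure elucidation and virtual-library construction: given `C9H18N2O4` you
want *all* chemically distinct connectivities — several billion for formulas of
that size — with no duplicates and no omissions, fast enough to enumerate and
filter them.

## Method

Generation follows a three-stage *canonical generation path*:

1. **Skeletons.** All connected simple graphs on the n heavy atoms, one per
   isomorphism class, with edge count in the range
   `[max(n−1, ⌈B/3⌉), min(B, n(n−1)/2)]` where `B = (Σ valence − #H)/2` is the
   bond total, and every degree at most the largest valence present.
   Implemented by McKay-style canonical augmentation (grow trees leaf by leaf,
   then add cycle edges; accept a child only when the new element lies in the
   canonically chosen deletable orbit), so generation is memoryless and
   streaming.
2. **Elements.** Assign element symbols to vertices, one assignment per orbit
   of Aut(G). The key device is the factorization **Aut(G) = N·M**: M, the
   *minor* subgroup, permutes leaves within *flowers* (maximal sets of leaves
   sharing a neighbour) and has order Π|F|!; N is the subgroup preserving a
   colouring that ranks each flower's leaves by vertex number. A label list L
   is the representative of its orbit iff its labels are non-increasing within
   each flower **and** γ(L) ≤ L for every γ ∈ N — and N is almost always tiny,
   which is what makes orbit selection cheap.
3. **Bonds.** Choose a multiplicity (1–3) for each edge, one assignment per
   orbit of the element-preserving subgroup (obtained by *filtering* N, never
   recomputed), under the valence cap at every atom and the global hydrogen
   balance Σ(valence − incident bonds) = #H. Hydrogens then attach uniquely.

Structural filters run at the earliest stage that can decide them: 5-cycle
count bounds, planarity and badlist B9 prune skeletons in stage 1 (all are
monotone under edge insertion, so a violating skeleton kills its whole
augmentation subtree); badlist B5 screens completed molecules.

## Worked example

```sh
$ isogen C2H6O
OCC
COC
2 molecules generated
```

The two lines are ethanol and dimethyl ether — the complete isomer list for
C2H6O. The count goes to stderr; `-u` suppresses structure output entirely,
`--sdf FILE` writes a V2000 SDfile instead. Filters mirror the generator's
option set, e.g. at most one 5-ring, planar only, badlists 5 and 9:

```sh
$ isogen C4H4O -u -p 0:1 -P -B 5,9
27 molecules generated
```

From Python:

```python
>>> from isogen import count_isomers, generate_molecules, write_smiles
>>> count_isomers("C6H6")
217
>>> next(write_smiles(m) for m in generate_molecules("C6H6"))
'C#CCCC#C'
```

217 is the textbook number of C6H6 constitutional isomers (Kekulé structures
counted as distinct — no aromaticity deduplication, see the methods note).

## Scope

Constitution only: no stereochemistry, charges, radicals, isotopes, or
aromatic perception; bond orders 1–3; one fixed valence per element per run
(defaults C4 N3 O2 S2 P3, halogens 1; override with `-v EL=VAL`).
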