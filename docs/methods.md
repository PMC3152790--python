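# Methods

## Data model

A `TypedGraph` is a finite vertex set with string ids, a label ("color")
per vertex, an optional list of possible attributes with at most one
assigned value, and edges `(u, v, e)` carrying an integer edge type `e`;
each type is globally directed or undirected. At most one edge of each
type may join a pair (parallel same-type edges are rejected, which is what
makes the power-of-two matrix encoding exactly invertible), and self-loops
are excluded. Molecular graphs reserve type 0 for directed *hierarchy*
(containment) edges and type 1 for undirected *bond* edges.

A `HierarchicalMoleculeGraph` additionally requires the hierarchy relation
to be acyclic. A vertex may declare itself its own parent in input files;
such declarations are normalized away on read, and roots are represented by
the absence of an outgoing hierarchy edge — this keeps the adjacency
encoding loop-free (zero diagonal) and the DAG check simple.
`classify_hierarchy` is total: a forest is a `strict_hierarchy`, a proper
DAG (some vertex with two parents, such as the shared tyrosine of
overlapping linear motifs) a `pseudo_hierarchy`, and a directed cycle
`invalid`. The *entity* flavor lists possible internal states without
fixing them; the *species* flavor requires every state to be assigned.
Labels are immutable identity; attributes are mutable state — deriving a
species from an entity assigns attributes and never touches labels.

The assigned attribute is folded into the vertex color for labeling
purposes (together with the label and the possible-attribute list), so two
species differing only in a phosphorylation state are never conflated.
This is a convention: one could instead treat attributes as invisible to
the labeler; folding is what makes species-level network generation
correct.

## Encoding

`encode_adjacency` writes entry `(i, j) = ∑ 2^e` over the types present
between `i` and `j`; undirected types contribute symmetrically, directed
types to the source row only. `decode_adjacency` rejects entries `≥ 2^m`,
non-zero diagonals, and asymmetric undirected bits (a corrupted matrix),
and inverts the encoding exactly.

`flatten` removes edge types by inserting one labeled vertex per edge
("h" for hierarchy, "b" for bond, `t<e>` otherwise). The single remaining
edge type is directed so that no information is lost: a directed edge
`x→y` becomes the path `x→v→y`, while an undirected edge sends both
endpoints into the inserted vertex (`x→v`, `y→v`), keeping the endpoints
interchangeable and the representation symmetric. The output has
`|V| + |E|` vertices and `2|E|` stored edges, and two typed graphs are
isomorphic exactly when their flattenings are — provided no original
vertex label collides with an inserted edge-vertex label (the test suite
checks the equivalence exhaustively on small graphs). Whether direction
should survive flattening is genuinely open — an undirected insertion
would erase the parent/child orientation of the hierarchy; preserving it
is what makes the transform lossless, so that is the choice made here.

## Refinement conventions

`coarsest_equitable_refinement` computes the unique coarsest generalized
equitable refinement with a splitter worklist (FIFO): a splitter cell `W`
partitions every current cell by the count key of type-wise edge counts
into `W` — `(out, in)` per directed type, a single incident count per
undirected type, types in increasing index order. The unordered result is
schedule-independent; the *cell order* is fixed by three conventions,
chosen so that the standard worked examples are reproduced literally:

* fragments of a **multi-vertex splitter** are ordered by count key
  **descending** — cells with higher degrees come before cells with lower
  degrees (so the chorded 5-cycle refines to `({v1,v3}, {v2}, {v4,v5})`);
* fragments of a **singleton splitter** are ordered **ascending** (this is
  what the reference leaf pair of the chorded 5-cycle implies: after
  individualizing `v1`, the vertex *not* adjacent to it precedes the
  adjacent one);
* after individualizing `x`, the new cell `{x}` is placed *before* the
  remainder `C \ {x}` and seeds the refinement worklist. Seeding with
  `{x}` or with `C \ {x}` produces the same splits (counts into the old
  cell are constant on every cell of an equitable partition) but opposite
  fragment orders; `{x}` is the choice consistent with the reference
  leaves.

All three conventions are functions of partition positions and counts
only, hence invariant under vertex relabeling — the property canonical
labeling actually needs.

## Canonical form

The search tree is rooted at the refined color partition (color classes
ordered by reverse-lexicographic color key). The target cell is always
the leftmost multi-vertex cell; candidate vertices are tried in a fixed
deterministic order. Each leaf (discrete partition) is associated with the
vertex ordering that reads its cells **last to first**; since refinement
places high-degree cells first, these orderings begin with low-degree
vertices and produce small serialized matrices. The canonical leaf is the
one with the lexicographically minimal indicator path and, among those,
the smallest row-major serialized matrix. The minimum is over the leaves
the search generates, not over all `n!` orderings: the globally minimal
ordering of a graph is in general not consistent with equitable
refinement (for the 5-path, the global minimum interleaves the degree-2
center between the ends and the mid vertices, which no cell order can
produce). The reversed reading makes the label coincide with the global
minimum on many simple families (stars, matchings, paths of length two)
without changing any of its guarantees. What matters and is tested: the
label is invariant under relabeling, equal labels imply isomorphism and
conversely, and the induced equivalence classes agree exactly with the
brute-force oracle's on exhaustive small-graph suites.

The full comparison key of a `CanonicalForm` records the edge-type table
and the color-class signature alongside the matrix, so graphs differing
only in labels or attributes are never conflated even when their matrices
coincide.

**Indicator.** The indicator of a node is the sequence of partition shapes
along its root path, where the shape of a partition counts its cells of
size 1, 2, … up to the largest occurring size. Shape sequences are
compared lexicographically (element-wise on shape tuples; a shorter
sequence that is a prefix of a longer one compares first, though leaf
paths can never be proper prefixes of one another — a discrete shape ends
a path). Being a pure function of partition shapes, the indicator is
invariant under any permutation of the vertices, which is what makes
skipping non-minimal branches sound.

**Automorphism pruning.** When two leaves yield equal matrices, the map
sending the i-th vertex of one ordering to the i-th of the other is an
automorphism; every discovered permutation is verified by a direct
edge-preservation check before use. At each node, a candidate lying in
the orbit of an already-explored candidate — under the subgroup generated
by discovered automorphisms that fix the individualized tuple pointwise —
roots a subtree equivalent to one already searched and is skipped. Full
orbit-partition bookkeeping (a stabilizer-chain data structure) would
prune more; the generator-closure used here is sound and sufficient for
the intended problem sizes.

`automorphism_count` exploits the group-invariance of the search tree:
the map `γ ↦ γ ∘ σ` is a bijection between the automorphism group and the
unpruned leaves whose matrix equals that of any fixed leaf `σ`, so the
count is exact. It is exponential for highly symmetric graphs and guarded
at 10 vertices by default.

## Brute-force oracle

`brute_canonical` returns the minimum serialized matrix over *all*
color-preserving vertex orderings (color classes in ascending key blocks),
and `brute_automorphisms` enumerates the automorphism group directly —
both by explicit permutation enumeration (numpy-accelerated), refusing
graphs above a configurable budget (default 8 vertices). The oracle is
deliberately independent of the search machinery: tests use it to verify
that the search label separates exactly the brute-force isomorphism
classes, that discovered automorphism counts are exact, and (orbit-
stabilizer) that `|Aut| × #distinct strings = #orderings`.

A note on a tempting but false identity: the search label does *not* equal
`brute_canonical`'s global minimum in general (see Canonical form above);
the two agree on which graphs are isomorphic, which is the property with
scientific content.

## Random graphs and the self-test

`sample_graph` draws, independently for each unordered vertex pair in
fixed (i < j) order: an undirected bond-type edge with probability 0.1, a
directed hierarchy-type edge with probability 0.05 (orientation uniform —
the sampling of orientations is a choice; the reference protocol does not
specify one), nothing with probability 0.85. These defaults, and the
reference problem size of 1000 graphs on 200 nodes, are the conditions of
the permutation self-test: each graph and a uniformly relabeled copy are
labeled independently and must agree. The full-size protocol runs in
under a minute and is part of the acceptance tests; scaled-down runs
(50 graphs on 20 nodes) appear in the unit tests. A master seed determines
every graph and permutation; per-trial seeds are logged on failure.

What the generator emulates — and what it does not: independent-pair
random graphs exercise the labeler on asymmetric, moderately dense
structures typical of the hard average case, but they are *not* molecular:
they have no hierarchy constraint (sampled type-0 edges may form cycles
through orientation, which the labeler handles but a molecule would not
exhibit), no attribute states, and uniform labels. Passing the self-test
therefore demonstrates relabeling-invariance of the full multi-edge-type
pipeline, not coverage of biochemical graph families; the molecular
fixtures (Lck, the TCR complex with its overlapping-motif DAG and
homodimer symmetry) cover those features deterministically.

## Numerical and degenerate-input choices

* All comparisons are integer/lexicographic; there is no floating point
  and no randomness anywhere in refinement or search.
* The empty graph has no canonical form (rejected); a single vertex has
  label `"0"`.
* Matrix entries stay below `2^m`; the oracle's uint8 fast path requires
  `m ≤ 8`, far above the two types used in practice.
* Binomial rate checks in the tests use 3σ bands; graph sizes there are
  chosen to keep the suite fast at equal statistical sensitivity.

## Known limitations

* No polynomial-time guarantee on adversarial highly symmetric graphs;
  the unpruned leaf count (and `automorphism_count`) is factorial on
  complete or empty same-color graphs.
* The optimized partial-refinement shortcuts of production Nauty are
  intentionally not replicated; the implementation favors a direct
  correspondence with the formal description.
* `flatten` assumes original vertex labels do not collide with the
  inserted "h"/"b"/`t<e>` labels.
* The TCR fixture ships two variants (drawing-faithful single-chain and
  fully expanded with intradimer disulfide bonds) because the reference
  drawing abbreviates repeated chains; neither is privileged.
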