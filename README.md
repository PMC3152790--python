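# hnauty

Canonical labeling and isomorphism testing for **hierarchical molecular
graphs** — labeled, attributed graphs with multiple edge types, as used to
represent multi-component biomolecules (proteins, receptor complexes,
chemical species) in rule-based models of cell signaling.

## The problem

Rule-based modeling frameworks represent a chemical species as a graph:
vertices are molecules, domains, motifs and residues; vertex *attributes*
carry internal states such as phosphorylation (`U`/`P`). Two kinds of
relationship coexist: *containment* (an SH2 domain is part of Lck; a
tyrosine is part of an ITAM) and *bonds* between components. Containment is
naturally a directed, acyclic relation — a tree for most proteins, a DAG
when linear motifs overlap (in the T cell receptor complex, tyrosine Y188
of CD3ε belongs to both a proline-rich sequence and an ITAM). Bonds are
undirected. A graph with directed *hierarchy* edges (type 0) and undirected
*bond* edges (type 1) captures both at once.

During network generation, every newly produced species graph must be
checked against all existing species for isomorphism. The efficient way is
a **canonical label**: a string equal for two graphs exactly when they are
isomorphic, so graph comparison becomes string comparison.

## The algorithm

A graph with `m` edge types is encoded, for a vertex ordering, as an
adjacency matrix with entries `∑ 2^e` over the edge types `e` present
between each pair — an undirected edge contributes to both symmetric
entries, a directed edge only to the source→target entry. With two types
the entries are 0, 1, 2, 3, and the encoding is exactly invertible.

The canonical ordering is found by **individualization and refinement**
with *generalized equitable partitions*: an ordered partition
`P = (V₁, …, V_k)` is generalized equitable when, for every edge type `e`
separately, `x, y ∈ V_i ⇒ d_e(x, V_j) = d_e(y, V_j)` for all cells `V_j`
(out- and in-counts both, for directed types). Every partition has a unique
coarsest generalized equitable refinement. The search tree starts from the
refined color partition; at each node the first multi-vertex cell is the
target, each of its vertices is individualized (`{x}` split off) and the
partition re-refined, until discrete partitions (vertex orderings) are
reached. Among the surviving leaves, the one with the minimal
shape-sequence indicator and the smallest serialized adjacency matrix is
the canonical form. Two prunings keep the tree small: permutations relating
equal-matrix leaves are graph **automorphisms**, and subtrees reachable
through the orbit of an already-explored choice are skipped; branches whose
indicator (an isomorphism-invariant sequence of partition shapes) cannot be
minimal are skipped.

## Worked example

```python
from hnauty import encode_adjacency, hnauty_canonical, are_isomorphic, automorphism_count
from hnauty.fixtures import lck_species, LCK_COMPONENT_ORDER, g1, g2

lck = lck_species()                     # Lck with Y505~P bound to SH2
print(encode_adjacency(lck.underlying, LCK_COMPONENT_ORDER).to_text())
```

```
	Lck	SH3	SH2	Y505	PTK	Y192	Y394
Lck	0	1	1	1	1	0	0
SH3	0	0	0	0	0	0	0
SH2	0	0	0	2	0	1	0
Y505	0	0	2	0	0	0	0
PTK	0	0	0	0	0	0	1
Y192	0	0	0	0	0	0	0
Y394	0	0	0	0	0	0	0
```

Row `Lck` shows the four components it contains (1 = hierarchy edge); the
symmetric 2-entries are the intramolecular SH2–Y505 bond. Canonical
labeling returns the canonical vertex ordering and the serialized matrix:

```python
form = hnauty_canonical(lck.underlying)
print(form.ordering)  # ('Lck', 'PTK', 'SH2', 'SH3', 'Y192', 'Y394', 'Y505')
print(form.label)     # '0 1 1 1 0 0 1 0 0 0 0 0 1 0 0 0 0 0 1 0 2 0 ...'
```

Any relabeled copy of the graph receives exactly the same label. The two
classic 5-vertex graphs with identical degree sequences are told apart,
and symmetry is quantified by the automorphism group:

```python
are_isomorphic(g1(), g2())   # False
automorphism_count(g2())     # 2
```

The same operations are available from the shell:

```bash
hnauty fixtures emit g2 > g2.graph
hnauty canon g2.graph --stats
hnauty iso g2.graph g2.graph
hnauty selftest --graphs 100 --nodes 50 --seed 1
```

## Layout

| module | contents |
| --- | --- |
| `hnauty.graph` | `TypedGraph`, `HierarchicalMoleculeGraph`, `OrderedPartition`, validation, hierarchy classification |
| `hnauty.encoding` | power-of-two adjacency matrices, decoding, edge→vertex flattening |
| `hnauty.refinement` | generalized equitable refinement, individualization |
| `hnauty.canon` | the search tree, automorphism discovery, pruning, canonical forms |
| `hnauty.oracle` | brute-force reference labeler and automorphism enumeration |
| `hnauty.randgen` | seeded random graphs, permutation self-test |
| `hnauty.io` / `hnauty.cli` | line-oriented graph/partition files, `hnauty` command |
| `hnauty.fixtures` | Lck, the TCR complex, the worked-example graphs |

See `docs/methods.md` for conventions, parameter choices and limitations.
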