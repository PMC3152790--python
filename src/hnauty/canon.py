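"""Canonical labeling of typed graphs by individualization and refinement.

The search tree is rooted at the coarsest generalized equitable refinement
of the initial (color) partition.  At each non-discrete node the first cell
with more than one vertex is the target cell; each of its vertices is
individualized in turn and the partition re-refined, producing one child
per choice.  Leaves are discrete partitions; the vertex ordering associated
with a leaf reads its cells *last to first*, and the leaf is scored by the
row-major serialization of the adjacency matrix written in that order.
Refinement places cells with higher degrees first, so the associated
orderings start with the vertices of lowest degree — the orderings whose
serialized matrices are small — and the canonical form is the surviving
leaf with the minimal indicator path and, among those, the smallest
serialized matrix.  The minimum is taken over the leaves the search
generates (not over all n! vertex orderings; the globally minimal ordering
is in general not refinement-consistent), which is exactly what canonical
labeling needs: the label is invariant under any relabeling of the input
because every ingredient (refinement, target choice, fragment order,
indicator) is itself relabeling-invariant, and two graphs share a label
only when a leaf of one and a leaf of the other induce an isomorphism.

Two pruning devices are available and sound:

* **automorphism pruning** — when two leaves yield equal matrices, the
  permutation relating them is a graph automorphism; subtrees reachable by
  individualizing a vertex in the orbit of an already-explored choice
  (under automorphisms fixing the current individualization tuple) are
  equivalent and skipped.
* **indicator pruning** — the indicator of a node is the sequence of
  partition shapes along its root path, a relabeling-invariant quantity;
  branches whose indicator compares worse than the current best leaf's can
  never supply the canonical leaf and are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .encoding import AdjacencyMatrix, encode_adjacency
from .graph import OrderedPartition, TypedGraph, partition_shape
from .refinement import coarsest_equitable_refinement, individualize_and_refine

__all__ = [
    "SearchNode",
    "SearchStats",
    "CanonicalForm",
    "PRUNING_MODES",
    "initial_partition",
    "enumerate_leaves",
    "discover_automorphism",
    "is_automorphism",
    "hnauty_canonical",
    "are_isomorphic",
    "automorphism_count",
]

PRUNING_MODES = ("none", "automorphism", "automorphism+indicator")

# Selection conventions (fixed; see docs/methods.md for the rationale):
# the canonical leaf minimizes the indicator path and, among those leaves,
# carries the lexicographically smallest serialized adjacency matrix under
# the reversed (last-cell-first) reading of the leaf.
_SMALLEST_INDICATOR = True
_SMALLEST_STRING = True


@dataclass(frozen=True)
class SearchNode:
    """A node of the search tree: the tuple of individualized vertices, the
    current (equitable) partition, and the indicator path from the root."""

    individualized: tuple[str, ...]
    partition: OrderedPartition
    indicator_path: tuple[tuple[int, ...], ...]

    @property
    def depth(self) -> int:
        return len(self.individualized)


@dataclass
class SearchStats:
    nodes_visited: int = 0
    leaves_generated: int = 0
    automorphisms_found: int = 0
    pruned_by_automorphism: int = 0
    pruned_by_indicator: int = 0


@dataclass(frozen=True)
class CanonicalForm:
    """Result of canonical labeling.

    ``ordering`` is the canonical vertex ordering (the discrete partition
    chosen by the search); ``matrix`` the adjacency matrix in that order;
    ``color_classes`` the initial color signature (color key and class
    size, in color order), recorded so that graphs differing only in labels
    or attributes are never conflated.
    """

    ordering: tuple[str, ...]
    matrix: AdjacencyMatrix
    color_classes: tuple[tuple[tuple, int], ...]
    num_edge_types: int
    directed: tuple[bool, ...]
    stats: SearchStats = field(compare=False, hash=False, default_factory=SearchStats)

    @property
    def label(self) -> str:
        """The serialized matrix, the comparison unit for canonical labels."""
        return " ".join(str(x) for x in self.matrix.serialized())

    def key(self) -> tuple:
        """Full comparison key: labels are only comparable between graphs
        with the same edge-type table and color signature."""
        return (
            self.num_edge_types,
            self.directed,
            self.color_classes,
            self.matrix.serialized(),
        )


def initial_partition(g: TypedGraph) -> OrderedPartition:
    """Color partition of the vertices: cells group vertices sharing a
    color key (label, possible attributes, assigned attribute), ordered by
    that key in reverse lexicographic order — invariant to the input vertex
    order, and consistent with the greater-first cell-ordering convention
    used by the refinement, so that the reversed reading of a leaf lists
    the color classes in ascending key order."""
    groups: dict[tuple, set[str]] = {}
    for v in g.vertices:
        groups.setdefault(g.color_key(v), set()).add(v)
    return OrderedPartition([groups[k] for k in sorted(groups, reverse=True)])


def _color_signature(g: TypedGraph) -> tuple[tuple[tuple, int], ...]:
    groups: dict[tuple, int] = {}
    for v in g.vertices:
        groups[g.color_key(v)] = groups.get(g.color_key(v), 0) + 1
    return tuple((k, groups[k]) for k in sorted(groups))


def _serialize(g: TypedGraph, ordering: tuple[str, ...]) -> tuple[int, ...]:
    idx = {v: i for i, v in enumerate(ordering)}
    n = len(ordering)
    flat = [0] * (n * n)
    for u, v, e in g.edges:
        flat[idx[u] * n + idx[v]] += 1 << e
        if not g.directed[e]:
            flat[idx[v] * n + idx[u]] += 1 << e
    return tuple(flat)


def is_automorphism(g: TypedGraph, perm: Mapping[str, str]) -> bool:
    """Direct check: ``perm`` preserves colors and every typed edge."""
    if set(perm) != set(g.vertices) or set(perm.values()) != set(g.vertices):
        return False
    if any(g.color_key(v) != g.color_key(perm[v]) for v in g.vertices):
        return False
    return all(g.has_edge(perm[u], perm[v], e) for u, v, e in g.edges)


def discover_automorphism(
    g: TypedGraph, leaf1: OrderedPartition, leaf2: OrderedPartition
) -> Optional[dict[str, str]]:
    """Automorphism relating two leaves, if their matrices coincide.

    Two leaf orderings produce equal adjacency matrices exactly when the
    map sending the i-th vertex of one ordering to the i-th vertex of the
    other is an automorphism; the discovered permutation is verified by a
    direct edge-preservation check before being returned.
    """
    o1, o2 = leaf1.ordering(), leaf2.ordering()
    if _serialize(g, o1) != _serialize(g, o2):
        return None
    gamma = {o1[i]: o2[i] for i in range(len(o1))}
    if not is_automorphism(g, gamma):  # pragma: no cover - defensive
        return None
    return gamma


class _Search:
    """Depth-first individualization-refinement search over one graph."""

    def __init__(self, g: TypedGraph, p0: Optional[OrderedPartition], pruning: str):
        if pruning not in PRUNING_MODES:
            raise ValueError(f"unknown pruning mode {pruning!r}")
        self.g = g
        self.pruning = pruning
        self.stats = SearchStats()
        self.gens: list[dict[str, str]] = []
        self.leaves: list[OrderedPartition] = []
        self.first: Optional[tuple[tuple[int, ...], tuple[str, ...]]] = None
        # best = (indicator_path, serialized, ordering)
        self.best: Optional[
            tuple[tuple[tuple[int, ...], ...], tuple[int, ...], tuple[str, ...]]
        ] = None
        base = initial_partition(g) if p0 is None else p0
        base.validate_over(g.vertices)
        self.root = coarsest_equitable_refinement(g, base)

    # -- selection ---------------------------------------------------------

    def _leaf_beats_best(self, path, serialized) -> bool:
        assert self.best is not None
        bpath, bser, _ = self.best
        if path != bpath:
            return (path < bpath) == _SMALLEST_INDICATOR
        if serialized != bser:
            return (serialized < bser) == _SMALLEST_STRING
        return False

    def _indicator_prunes(self, path) -> bool:
        """True when no leaf under a node with this indicator prefix can be
        selected over the current best leaf."""
        if self.best is None:
            return False
        ref = self.best[0][: len(path)]
        if path == ref:
            return False
        return (path > ref) == _SMALLEST_INDICATOR

    # -- automorphism bookkeeping -----------------------------------------

    def _orbit_closure(self, seeds: list[str], fixed: tuple[str, ...]) -> set[str]:
        relevant = [
            gam for gam in self.gens if all(gam[v] == v for v in fixed)
        ]
        reach = set(seeds)
        if not relevant:
            return reach
        frontier = list(seeds)
        while frontier:
            v = frontier.pop()
            for gam in relevant:
                w = gam[v]
                if w not in reach:
                    reach.add(w)
                    frontier.append(w)
        return reach

    def _record_leaf(self, node: SearchNode) -> None:
        self.stats.leaves_generated += 1
        self.leaves.append(node.partition)
        # the ordering associated with a leaf reads its cells last-to-first
        ordering = node.partition.ordering()[::-1]
        serialized = _serialize(self.g, ordering)
        if self.first is None:
            self.first = (serialized, ordering)
        else:
            for ref_ser, ref_ord in (
                (self.first[0], self.first[1]),
                (self.best[1], self.best[2]) if self.best else (None, None),
            ):
                if ref_ser is not None and serialized == ref_ser and ordering != ref_ord:
                    gamma = {ref_ord[i]: ordering[i] for i in range(len(ordering))}
                    if is_automorphism(self.g, gamma) and gamma not in self.gens:
                        self.gens.append(gamma)
                        self.stats.automorphisms_found += 1
                    break
        if self.best is None or self._leaf_beats_best(node.indicator_path, serialized):
            self.best = (node.indicator_path, serialized, ordering)

    # -- traversal ---------------------------------------------------------

    def run(self) -> None:
        self._visit(SearchNode((), self.root, (partition_shape(self.root),)))

    def _visit(self, node: SearchNode) -> None:
        self.stats.nodes_visited += 1
        if node.partition.is_discrete:
            self._record_leaf(node)
            return
        target = next(c for c in node.partition.cells if len(c) > 1)
        candidates = sorted(target, key=self.g.index)
        processed: list[str] = []
        for x in candidates:
            if self.pruning != "none" and processed:
                if x in self._orbit_closure(processed, node.individualized):
                    self.stats.pruned_by_automorphism += 1
                    continue
            child_partition = individualize_and_refine(self.g, node.partition, x)
            child = SearchNode(
                node.individualized + (x,),
                child_partition,
                node.indicator_path + (partition_shape(child_partition),),
            )
            if self.pruning == "automorphism+indicator" and self._indicator_prunes(
                child.indicator_path
            ):
                self.stats.pruned_by_indicator += 1
                continue
            self._visit(child)
            processed.append(x)


def enumerate_leaves(
    g: TypedGraph,
    p0: Optional[OrderedPartition] = None,
    pruning: str = "none",
    stats: Optional[SearchStats] = None,
) -> list[OrderedPartition]:
    """All discrete partitions produced by the search (surviving leaves).

    With ``pruning="none"`` every leaf reachable by individualizing each
    element of the first non-singleton cell at every level is returned, in
    depth-first order.
    """
    search = _Search(g, p0, pruning)
    search.run()
    if stats is not None:
        stats.__dict__.update(search.stats.__dict__)
    return search.leaves


def hnauty_canonical(
    g: TypedGraph,
    p0: Optional[OrderedPartition] = None,
    pruning: str = "automorphism+indicator",
) -> CanonicalForm:
    """Canonical form of a typed graph.

    The label — the serialized adjacency matrix of the graph written in the
    canonical vertex order — is identical for isomorphic inputs and
    distinct for non-isomorphic inputs of the same color signature, and is
    deterministic for a fixed input.
    """
    if g.n == 0:
        raise ValueError("cannot canonically label the empty graph")
    search = _Search(g, p0, pruning)
    search.run()
    assert search.best is not None
    ordering = search.best[2]
    return CanonicalForm(
        ordering,
        encode_adjacency(g, ordering),
        _color_signature(g),
        g.num_edge_types,
        g.directed,
        search.stats,
    )


def are_isomorphic(g1: TypedGraph, g2: TypedGraph) -> bool:
    """Isomorphism verdict via canonical labels.

    True exactly when some bijection of the vertex sets preserves colors
    and, for every edge type, maps the type-restricted edge set of one
    graph onto the other's.
    """
    if g1.num_edge_types != g2.num_edge_types or g1.directed != g2.directed:
        raise ValueError("graphs have incompatible edge-type tables")
    if g1.n != g2.n or len(g1.edges) != len(g2.edges):
        return False
    if _color_signature(g1) != _color_signature(g2):
        return False
    return hnauty_canonical(g1).key() == hnauty_canonical(g2).key()


def automorphism_count(g: TypedGraph, max_vertices: int = 10) -> int:
    """Order of the automorphism group.

    Every unpruned leaf whose matrix equals a reference leaf's matrix
    corresponds to exactly one automorphism (the search tree is invariant
    under the group), so the count is the number of such leaves.  Factorial
    for completely symmetric graphs, hence the size guard.
    """
    if g.n > max_vertices:
        raise ValueError(
            f"automorphism_count by exhaustive search is limited to "
            f"{max_vertices} vertices (got {g.n})"
        )
    leaves = enumerate_leaves(g, pruning="none")
    ref = _serialize(g, leaves[0].ordering())
    return sum(1 for leaf in leaves if _serialize(g, leaf.ordering()) == ref)
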