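"""Core graph types: typed graphs, hierarchical molecule graphs, ordered partitions.

A :class:`TypedGraph` is a vertex-labeled, optionally attributed graph whose
edges each carry an integer *edge type*; every type is globally declared
directed or undirected.  Molecular graphs use two types: type 0 ("hierarchy",
directed, meaning *contains*) and type 1 ("bond", undirected, a molecular
bond between components).  A hierarchical molecule graph additionally
requires the hierarchy relation to be acyclic: a tree/forest for a strict
hierarchy, or any DAG for a pseudo-hierarchy (a part, such as a tyrosine
shared by two overlapping linear motifs, may have two parents).

Vertex ids are opaque strings; the *label* carries chemical meaning and two
distinct vertices may share a label.  Each vertex has a (possibly empty)
list of possible attributes (internal states, e.g. ``U``/``P`` for a
phosphorylation site) and at most one assigned attribute.  Labels never
change during a simulation; attributes may.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "TypedGraph",
    "HierarchicalMoleculeGraph",
    "OrderedPartition",
    "HIERARCHY",
    "BOND",
    "build_graph",
    "classify_hierarchy",
    "assign_attributes",
    "partition_shape",
    "is_refinement",
]

#: Edge type reserved for directed containment ("contains") edges.
HIERARCHY = 0
#: Edge type reserved for undirected molecular bond edges.
BOND = 1

# adjacency entry kinds
OUT = 0  # outgoing directed edge, or incident undirected edge
IN = 1  # incoming directed edge


class TypedGraph:
    """Immutable graph with typed, per-type directed/undirected edges.

    Parameters
    ----------
    vertices
        Ordered vertex ids (unique strings).  The order is remembered and
        used only as a deterministic tie-break; no algorithm result depends
        on it except through explicitly order-sensitive operations.
    labels
        Vertex id -> label string (the vertex "color").
    edges
        Triples ``(u, v, edge_type)``.  At most one edge of each type may
        join a vertex pair; undirected-type edges are stored as a single
        canonical (sorted) pair.
    directed
        Per-type directedness flags, index = edge type.
    possible_attributes, attributes
        Optional internal-state machinery; an assigned attribute must be
        drawn from the vertex's possible list.
    """

    __slots__ = (
        "vertices",
        "labels",
        "possible_attributes",
        "attributes",
        "edges",
        "directed",
        "_index",
        "_adj",
    )

    def __init__(
        self,
        vertices: Sequence[str],
        labels: Mapping[str, str],
        edges: Iterable[tuple[str, str, int]],
        directed: Sequence[bool],
        possible_attributes: Optional[Mapping[str, Sequence[str]]] = None,
        attributes: Optional[Mapping[str, Optional[str]]] = None,
    ):
        self.vertices: tuple[str, ...] = tuple(vertices)
        if len(set(self.vertices)) != len(self.vertices):
            raise ValueError("duplicate vertex ids")
        vset = set(self.vertices)
        if set(labels) - vset:
            raise ValueError("labels refer to undeclared vertices")
        self.labels: dict[str, str] = {v: str(labels.get(v, "")) for v in self.vertices}
        possible_attributes = possible_attributes or {}
        attributes = attributes or {}
        if set(possible_attributes) - vset or set(attributes) - vset:
            raise ValueError("attribute maps refer to undeclared vertices")
        self.possible_attributes: dict[str, tuple[str, ...]] = {
            v: tuple(possible_attributes.get(v, ())) for v in self.vertices
        }
        self.attributes: dict[str, Optional[str]] = {
            v: attributes.get(v) for v in self.vertices
        }
        for v, a in self.attributes.items():
            if a is not None and a not in self.possible_attributes[v]:
                raise ValueError(
                    f"attribute {a!r} of vertex {v!r} not in its possible list "
                    f"{self.possible_attributes[v]!r}"
                )
        self.directed: tuple[bool, ...] = tuple(bool(d) for d in directed)
        norm: set[tuple[str, str, int]] = set()
        seen_pairs: set[tuple[str, str, int]] = set()
        for u, v, e in edges:
            if u not in vset or v not in vset:
                raise ValueError(f"edge ({u!r}, {v!r}, {e}) has an undeclared endpoint")
            e = int(e)
            if not 0 <= e < len(self.directed):
                raise ValueError(f"edge type {e} out of range (m={len(self.directed)})")
            if u == v:
                raise ValueError(f"self-loop on vertex {u!r} is not allowed")
            key = (u, v, e) if self.directed[e] else (min(u, v), max(u, v), e)
            if key in seen_pairs:
                raise ValueError(f"duplicate type-{e} edge between {u!r} and {v!r}")
            seen_pairs.add(key)
            norm.add(key)
        self.edges: frozenset[tuple[str, str, int]] = frozenset(norm)
        self._index: dict[str, int] = {v: i for i, v in enumerate(self.vertices)}
        self._adj: Optional[dict[str, list[tuple[str, int, int]]]] = None

    # ------------------------------------------------------------------ basic

    @property
    def num_edge_types(self) -> int:
        return len(self.directed)

    @property
    def n(self) -> int:
        return len(self.vertices)

    def index(self, v: str) -> int:
        return self._index[v]

    def color_key(self, v: str) -> tuple:
        """Full color of a vertex: label, possible attributes, assigned state.

        The assigned attribute is folded into the color, so two species
        graphs differing only in an internal state are never conflated.
        """
        a = self.attributes[v]
        return (self.labels[v], self.possible_attributes[v], "" if a is None else a)

    def has_edge(self, u: str, v: str, e: int) -> bool:
        if self.directed[e]:
            return (u, v, e) in self.edges
        return (min(u, v), max(u, v), e) in self.edges

    def adjacency(self) -> dict[str, list[tuple[str, int, int]]]:
        """Incidence lists ``v -> [(neighbor, edge_type, kind)]``.

        ``kind`` is :data:`OUT` for an outgoing directed edge or an incident
        undirected edge, :data:`IN` for an incoming directed edge.
        """
        if self._adj is None:
            adj: dict[str, list[tuple[str, int, int]]] = {v: [] for v in self.vertices}
            for u, v, e in self.edges:
                if self.directed[e]:
                    adj[u].append((v, e, OUT))
                    adj[v].append((u, e, IN))
                else:
                    adj[u].append((v, e, OUT))
                    adj[v].append((u, e, OUT))
            self._adj = adj
        return self._adj

    def degree(self, v: str, edge_type: Optional[int] = None) -> int:
        """Number of incident edges, optionally restricted to one type."""
        return sum(
            1 for _, e, _ in self.adjacency()[v] if edge_type is None or e == edge_type
        )

    # ------------------------------------------------------- transformations

    def permuted(
        self,
        mapping: Mapping[str, str],
        new_order: Optional[Sequence[str]] = None,
    ) -> "TypedGraph":
        """Relabel vertices through a bijection ``old id -> new id``.

        ``new_order`` fixes the stored vertex order of the result; by
        default the images keep the positions of their preimages.
        """
        if set(mapping) != set(self.vertices) or len(set(mapping.values())) != self.n:
            raise ValueError("mapping is not a bijection on the vertex set")
        order = (
            tuple(new_order)
            if new_order is not None
            else tuple(mapping[v] for v in self.vertices)
        )
        return TypedGraph(
            order,
            {mapping[v]: self.labels[v] for v in self.vertices},
            [(mapping[u], mapping[v], e) for u, v, e in self.edges],
            self.directed,
            {mapping[v]: self.possible_attributes[v] for v in self.vertices},
            {mapping[v]: self.attributes[v] for v in self.vertices},
        )

    def with_attributes(self, assignment: Mapping[str, str]) -> "TypedGraph":
        attrs = dict(self.attributes)
        attrs.update(assignment)
        return TypedGraph(
            self.vertices,
            self.labels,
            self.edges,
            self.directed,
            self.possible_attributes,
            attrs,
        )

    def to_networkx(self):
        """Export as a :class:`networkx.MultiDiGraph` (undirected-type edges
        become symmetric arc pairs; each arc carries ``edge_type``)."""
        import networkx as nx

        g = nx.MultiDiGraph()
        for v in self.vertices:
            g.add_node(
                v,
                label=self.labels[v],
                possible_attributes=self.possible_attributes[v],
                attribute=self.attributes[v],
            )
        for u, v, e in sorted(self.edges):
            g.add_edge(u, v, edge_type=e)
            if not self.directed[e]:
                g.add_edge(v, u, edge_type=e)
        return g

    # ------------------------------------------------------------- equality

    def structure_key(self) -> tuple:
        return (
            self.vertices,
            tuple(sorted(self.labels.items())),
            tuple(sorted((v, p) for v, p in self.possible_attributes.items())),
            tuple(sorted((v, a or "") for v, a in self.attributes.items())),
            tuple(sorted(self.edges)),
            self.directed,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, TypedGraph):
            return NotImplemented
        return self.structure_key() == other.structure_key()

    def __hash__(self) -> int:
        return hash(self.structure_key())

    def __repr__(self) -> str:
        return (
            f"TypedGraph(n={self.n}, m={self.num_edge_types}, "
            f"|E|={len(self.edges)})"
        )


class HierarchicalMoleculeGraph:
    """A :class:`TypedGraph` whose type-0 edges form an acyclic containment
    relation (hierarchy) and whose type-1 edges are molecular bonds.

    ``flavor`` distinguishes a molecular *entity* graph (internal states
    listed but unassigned) from a chemical *species* graph, in which every
    vertex with a non-empty possible-attribute list carries exactly one
    assigned attribute.
    """

    __slots__ = ("underlying", "flavor")

    def __init__(self, underlying: TypedGraph, flavor: str = "entity"):
        if flavor not in ("entity", "species"):
            raise ValueError("flavor must be 'entity' or 'species'")
        if underlying.num_edge_types < 2 or underlying.directed[HIERARCHY] is not True:
            raise ValueError("hierarchy edge type 0 must be declared directed")
        if underlying.directed[BOND] is not False:
            raise ValueError("bond edge type 1 must be declared undirected")
        kind = classify_hierarchy(underlying)
        if kind == "invalid":
            raise ValueError("hierarchy edges contain a directed cycle")
        if flavor == "species":
            for v in underlying.vertices:
                if underlying.possible_attributes[v] and underlying.attributes[v] is None:
                    raise ValueError(
                        f"species graph requires an assigned attribute for {v!r}"
                    )
        self.underlying = underlying
        self.flavor = flavor

    def __getattr__(self, name):  # delegate read-only graph API
        return getattr(self.underlying, name)

    def __eq__(self, other) -> bool:
        if not isinstance(other, HierarchicalMoleculeGraph):
            return NotImplemented
        return self.flavor == other.flavor and self.underlying == other.underlying

    def __hash__(self) -> int:
        return hash((self.flavor, self.underlying))

    def parents(self, v: str) -> list[str]:
        """Hierarchy parents of ``v`` (sources of incoming type-0 edges)."""
        return sorted(u for u, w, e in self.underlying.edges if e == HIERARCHY and w == v)

    def roots(self) -> list[str]:
        return [v for v in self.underlying.vertices if not self.parents(v)]

    def __repr__(self) -> str:
        return f"HierarchicalMoleculeGraph({self.underlying!r}, flavor={self.flavor!r})"


class OrderedPartition:
    """An ordered sequence of disjoint non-empty vertex cells covering V.

    A partition is *discrete* when every cell is a singleton (equivalently,
    it encodes a vertex ordering / permutation) and *trivial* when it has a
    single cell.
    """

    __slots__ = ("cells",)

    def __init__(self, cells: Iterable[Iterable[str]]):
        self.cells: tuple[frozenset[str], ...] = tuple(frozenset(c) for c in cells)
        if any(not c for c in self.cells):
            raise ValueError("partition contains an empty cell")
        total = sum(len(c) for c in self.cells)
        if len(frozenset().union(*self.cells) if self.cells else frozenset()) != total:
            raise ValueError("partition cells are not pairwise disjoint")

    @property
    def universe(self) -> frozenset[str]:
        return frozenset().union(*self.cells) if self.cells else frozenset()

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    def __getitem__(self, i):
        return self.cells[i]

    @property
    def is_discrete(self) -> bool:
        return all(len(c) == 1 for c in self.cells)

    @property
    def is_trivial(self) -> bool:
        return len(self.cells) == 1

    def ordering(self) -> tuple[str, ...]:
        """The vertex ordering encoded by a discrete partition."""
        if not self.is_discrete:
            raise ValueError("only a discrete partition encodes an ordering")
        return tuple(next(iter(c)) for c in self.cells)

    def validate_over(self, vertices: Iterable[str]) -> None:
        if self.universe != frozenset(vertices):
            raise ValueError("partition does not cover the expected vertex set")

    def __eq__(self, other) -> bool:
        if not isinstance(other, OrderedPartition):
            return NotImplemented
        return self.cells == other.cells

    def __hash__(self) -> int:
        return hash(self.cells)

    def __repr__(self) -> str:
        body = ", ".join("{" + ",".join(sorted(c)) + "}" for c in self.cells)
        return f"({body})"


# ---------------------------------------------------------------- operations


def build_graph(
    vertex_specs: Iterable,
    edge_specs: Iterable[tuple[str, str, int]],
    type_directedness: Sequence,
) -> TypedGraph:
    """Validating constructor from plain specs.

    ``vertex_specs`` items are ``(id, label)``, ``(id, label, possible)`` or
    ``(id, label, possible, assigned)``.  ``type_directedness`` entries may
    be booleans or the strings ``"directed"`` / ``"undirected"``.
    """
    ids: list[str] = []
    labels: dict[str, str] = {}
    possible: dict[str, tuple[str, ...]] = {}
    attrs: dict[str, Optional[str]] = {}
    for spec in vertex_specs:
        spec = tuple(spec)
        vid, label = spec[0], spec[1]
        if vid in labels:
            raise ValueError(f"duplicate vertex id {vid!r}")
        ids.append(vid)
        labels[vid] = label
        possible[vid] = tuple(spec[2]) if len(spec) > 2 else ()
        attrs[vid] = spec[3] if len(spec) > 3 else None
    directed = []
    for d in type_directedness:
        if isinstance(d, str):
            if d not in ("directed", "undirected"):
                raise ValueError(f"unknown directedness {d!r}")
            directed.append(d == "directed")
        else:
            directed.append(bool(d))
    return TypedGraph(ids, labels, edge_specs, directed, possible, attrs)


def classify_hierarchy(g) -> str:
    """Classify the containment relation of a typed graph.

    Returns ``"strict_hierarchy"`` if every vertex has at most one parent
    and the relation is acyclic (a forest), ``"pseudo_hierarchy"`` for an
    acyclic relation with a multiply-contained vertex (a proper DAG), and
    ``"invalid"`` if the hierarchy edges contain a directed cycle.  The
    classification is total and invariant under vertex renaming.
    """
    if isinstance(g, HierarchicalMoleculeGraph):
        g = g.underlying
    children: dict[str, list[str]] = {v: [] for v in g.vertices}
    indeg: dict[str, int] = {v: 0 for v in g.vertices}
    for u, v, e in g.edges:
        if e == HIERARCHY:
            children[u].append(v)
            indeg[v] += 1
    # Kahn's algorithm for acyclicity
    stack = [v for v in g.vertices if indeg[v] == 0]
    remaining = dict(indeg)
    seen = 0
    while stack:
        u = stack.pop()
        seen += 1
        for w in children[u]:
            remaining[w] -= 1
            if remaining[w] == 0:
                stack.append(w)
    if seen != len(g.vertices):
        return "invalid"
    if any(d > 1 for d in indeg.values()):
        return "pseudo_hierarchy"
    return "strict_hierarchy"


def assign_attributes(
    entity: HierarchicalMoleculeGraph, assignment: Mapping[str, str]
) -> HierarchicalMoleculeGraph:
    """Derive a chemical species graph from a molecular entity graph.

    ``assignment`` must give exactly one attribute, drawn from the vertex's
    possible list, to every vertex that has a non-empty possible list.
    Labels are left untouched; only attributes are set.
    """
    if entity.flavor != "entity":
        raise ValueError("assign_attributes expects an entity-flavored graph")
    g = entity.underlying
    attributed = {v for v in g.vertices if g.possible_attributes[v]}
    if set(assignment) != attributed:
        missing = attributed - set(assignment)
        extra = set(assignment) - attributed
        raise ValueError(
            f"assignment must cover exactly the attributed vertices "
            f"(missing={sorted(missing)}, unexpected={sorted(extra)})"
        )
    for v, a in assignment.items():
        if a not in g.possible_attributes[v]:
            raise ValueError(
                f"attribute {a!r} not in possible list of {v!r}: "
                f"{g.possible_attributes[v]!r}"
            )
    return HierarchicalMoleculeGraph(g.with_attributes(assignment), flavor="species")


def partition_shape(p: OrderedPartition) -> tuple[int, ...]:
    """Shape of a partition: entry *k* (1-based) counts the cells of size *k*.

    The tuple is truncated at the largest occurring cell size, so the
    partition ``({0,1},{6},{5},{2,3,4,7})`` has shape ``(2, 1, 0, 1)``.
    """
    if not p.cells:
        return ()
    largest = max(len(c) for c in p.cells)
    shape = [0] * largest
    for c in p.cells:
        shape[len(c) - 1] += 1
    return tuple(shape)


def is_refinement(p: OrderedPartition, q: OrderedPartition) -> bool:
    """Whether ordered partition ``p`` refines ordered partition ``q``.

    Beyond cell containment, the ordered condition must hold: the first cell
    of ``p`` lies in the first cell of ``q``, and consecutive cells of ``p``
    land in the same cell of ``q`` or the next one.
    """
    if p.universe != q.universe:
        raise ValueError("partitions are over different vertex sets")
    j = 0
    for cell in p.cells:
        if cell <= q.cells[j]:
            continue
        if j + 1 < len(q.cells) and cell <= q.cells[j + 1]:
            j += 1
            continue
        return False
    # every q-cell must have been consumed (guaranteed by equal universes
    # and disjointness once the walk succeeds)
    return j == len(q.cells) - 1 or len(q.cells) == 0
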