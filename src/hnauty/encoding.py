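"""Multi-edge-type adjacency encoding and the edge-to-vertex flattening.

A typed graph with ``m`` edge types is encoded, for a chosen vertex order,
as an n x n integer matrix whose ``(i, j)`` entry is the sum of ``2**e``
over the edge types ``e`` present between vertex ``i`` and vertex ``j``.
An undirected-type edge contributes to both symmetric entries; a directed
edge from ``i`` to ``j`` contributes only to ``(i, j)``.  With hierarchy
edges as type 0 and bond edges as type 1 the possible entries of a
molecular graph are 0, 1, 2 and 3 (3 = hierarchy edge plus bond edge
between the same pair).  Because at most one edge of each type may join a
pair, the encoding is exactly invertible.

The row-major integer sequence of such a matrix is the string compared by
the canonical-labeling machinery in :mod:`hnauty.canon`.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from .graph import TypedGraph

__all__ = [
    "AdjacencyMatrix",
    "encode_adjacency",
    "decode_adjacency",
    "flatten",
    "adjacency_dict",
    "from_adjacency_dict",
]


class AdjacencyMatrix:
    """An n x n integer matrix over an explicit vertex order."""

    __slots__ = ("order", "entries")

    def __init__(self, order: Sequence[str], entries: Sequence[Sequence[int]]):
        self.order: tuple[str, ...] = tuple(order)
        n = len(self.order)
        if len(entries) != n or any(len(row) != n for row in entries):
            raise ValueError("entries must form a square matrix over the order")
        self.entries: tuple[tuple[int, ...], ...] = tuple(
            tuple(int(x) for x in row) for row in entries
        )

    def entry(self, u: str, v: str) -> int:
        i, j = self.order.index(u), self.order.index(v)
        return self.entries[i][j]

    def serialized(self) -> tuple[int, ...]:
        """Row-major flattening; the unit of label comparison."""
        return tuple(x for row in self.entries for x in row)

    def to_text(self) -> str:
        """Tab-separated dump with a header row/column of vertex ids."""
        lines = ["\t" + "\t".join(self.order)]
        for v, row in zip(self.order, self.entries):
            lines.append(v + "\t" + "\t".join(str(x) for x in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "AdjacencyMatrix":
        rows = [line.split("\t") for line in text.strip("\n").split("\n")]
        order = rows[0][1:]
        entries = [[int(x) for x in row[1:]] for row in rows[1:]]
        if [row[0] for row in rows[1:]] != order:
            raise ValueError("row ids do not match the header column order")
        return cls(order, entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AdjacencyMatrix):
            return NotImplemented
        return self.order == other.order and self.entries == other.entries

    def __hash__(self) -> int:
        return hash((self.order, self.entries))

    def __repr__(self) -> str:
        return f"AdjacencyMatrix(order={self.order!r})"


def encode_adjacency(g: TypedGraph, order: Optional[Sequence[str]] = None) -> AdjacencyMatrix:
    """Encode ``g`` over ``order`` (default: the stored vertex order)."""
    order = tuple(order) if order is not None else g.vertices
    if sorted(order) != sorted(g.vertices) or len(set(order)) != len(order):
        raise ValueError("order is not a permutation of the graph's vertices")
    idx = {v: i for i, v in enumerate(order)}
    n = len(order)
    rows = [[0] * n for _ in range(n)]
    for u, v, e in g.edges:
        rows[idx[u]][idx[v]] += 1 << e
        if not g.directed[e]:
            rows[idx[v]][idx[u]] += 1 << e
    return AdjacencyMatrix(order, rows)


def decode_adjacency(
    matrix: AdjacencyMatrix,
    labels: Mapping[str, str],
    type_directedness: Sequence[bool],
    possible_attributes: Optional[Mapping[str, Sequence[str]]] = None,
    attributes: Optional[Mapping[str, Optional[str]]] = None,
) -> TypedGraph:
    """Reconstruct the typed graph encoded by ``matrix``.

    Every entry must be below ``2**m`` and, for each undirected type, the
    corresponding bit must be symmetric across the diagonal; an asymmetric
    undirected bit signals a corrupted matrix and is rejected.  Re-encoding
    the result over the same order reproduces ``matrix`` exactly.
    """
    m = len(type_directedness)
    order = matrix.order
    n = len(order)
    edges: list[tuple[str, str, int]] = []
    for i in range(n):
        for j in range(n):
            entry = matrix.entries[i][j]
            if entry < 0 or entry >= (1 << m):
                raise ValueError(
                    f"entry {entry} at ({order[i]!r}, {order[j]!r}) is not "
                    f"representable with {m} edge types"
                )
            if i == j and entry:
                raise ValueError(f"non-zero diagonal entry at {order[i]!r}")
            for e in range(m):
                if not entry >> e & 1:
                    continue
                if type_directedness[e]:
                    edges.append((order[i], order[j], e))
                else:
                    if not matrix.entries[j][i] >> e & 1:
                        raise ValueError(
                            f"undirected type-{e} bit at ({order[i]!r}, "
                            f"{order[j]!r}) is not symmetric"
                        )
                    if i < j:
                        edges.append((order[i], order[j], e))
    return TypedGraph(
        order, labels, edges, type_directedness, possible_attributes, attributes
    )


#: labels given to inserted edge-vertices, per edge type
FLATTEN_LABELS = {0: "h", 1: "b"}


def flatten(g: TypedGraph) -> TypedGraph:
    """Replace typed edges by labeled vertices, leaving a single edge type.

    Each original edge of type ``l`` between ``x`` and ``y`` is deleted and
    replaced by a new vertex labeled for ``l`` ("h" for a hierarchy edge,
    "b" for a bond, ``t<l>`` otherwise) joined to both endpoints, giving a
    bipartite graph with ``|V| + |E|`` vertices and ``2 |E|`` stored edges.
    The single output type is directed so that edge direction survives: a
    directed edge ``x -> y`` becomes the path ``x -> v -> y``, while an
    undirected edge sends both endpoints into the new vertex (``x -> v`` and
    ``y -> v``), keeping the two endpoints interchangeable.  Two typed
    graphs are isomorphic exactly when their flattenings are, provided no
    original vertex label collides with an inserted edge-vertex label.
    """
    vertices = list(g.vertices)
    labels = dict(g.labels)
    possible = dict(g.possible_attributes)
    attrs = dict(g.attributes)
    new_edges: list[tuple[str, str, int]] = []
    for k, (u, v, e) in enumerate(sorted(g.edges)):
        w = f"__edge{k}"
        vertices.append(w)
        labels[w] = FLATTEN_LABELS.get(e, f"t{e}")
        possible[w] = ()
        attrs[w] = None
        if g.directed[e]:
            new_edges.append((u, w, 0))
            new_edges.append((w, v, 0))
        else:
            new_edges.append((u, w, 0))
            new_edges.append((v, w, 0))
    return TypedGraph(vertices, labels, new_edges, (True,), possible, attrs)


def adjacency_dict(g: TypedGraph) -> dict[str, dict[str, list[int]]]:
    """Nested mapping ``vertex -> neighbor -> sorted list of edge types``.

    Directed edges appear only under their source vertex; undirected edges
    under both endpoints.
    """
    out: dict[str, dict[str, list[int]]] = {v: {} for v in g.vertices}
    for u, v, e in sorted(g.edges):
        out[u].setdefault(v, []).append(e)
        if not g.directed[e]:
            out[v].setdefault(u, []).append(e)
    for nbrs in out.values():
        for types in nbrs.values():
            types.sort()
    return out


def from_adjacency_dict(
    mapping: Mapping[str, Mapping[str, Sequence[int]]],
    labels: Mapping[str, str],
    type_directedness: Sequence[bool],
    possible_attributes: Optional[Mapping[str, Sequence[str]]] = None,
    attributes: Optional[Mapping[str, Optional[str]]] = None,
    order: Optional[Sequence[str]] = None,
) -> TypedGraph:
    """Inverse of :func:`adjacency_dict`."""
    order = tuple(order) if order is not None else tuple(sorted(mapping))
    edges: set[tuple[str, str, int]] = set()
    for u, nbrs in mapping.items():
        for v, types in nbrs.items():
            for e in types:
                if type_directedness[e]:
                    edges.add((u, v, e))
                else:
                    edges.add((min(u, v), max(u, v), e))
    return TypedGraph(
        order, labels, edges, type_directedness, possible_attributes, attributes
    )
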