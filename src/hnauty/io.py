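"""Line-oriented graph and partition files.

Graph files are UTF-8 text; ``#`` starts a comment and blank lines are
ignored.  Three record kinds:

``T <type:int> <directed|undirected>``
    Declares an edge type (types must be 0..m-1, each declared once).
``V <id> <label> [~attr1,attr2,...] [=assigned]``
    Declares a vertex with its label, an optional list of possible
    attributes, and an optional assigned attribute.
``E <src_id> <dst_id> <type:int>``
    Declares an edge.  A hierarchy self-edge ``E v v 0`` (the permissible
    "v is its own parent" declaration for a root) is accepted and
    normalized away: roots are represented by the absence of an outgoing
    hierarchy edge.

Partition files hold one cell per line as comma-separated vertex ids,
top-to-bottom in cell order.
"""

from __future__ import annotations

import os
from typing import Union

from .graph import HIERARCHY, OrderedPartition, TypedGraph

__all__ = [
    "parse_graph",
    "read_graph",
    "format_graph",
    "write_graph",
    "parse_partition",
    "read_partition",
    "format_partition",
    "write_partition",
]

PathLike = Union[str, "os.PathLike[str]"]


class GraphFileError(ValueError):
    """Malformed graph or partition file; carries the offending line."""

    def __init__(self, message: str, line_no: int | None = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


def parse_graph(text: str) -> TypedGraph:
    directedness: dict[int, bool] = {}
    vertices: list[tuple] = []
    seen_ids: set[str] = set()
    edges: list[tuple[str, str, int]] = []
    edge_lines: list[int] = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        kind = fields[0]
        if kind == "T":
            if len(fields) != 3 or fields[2] not in ("directed", "undirected"):
                raise GraphFileError(
                    "expected 'T <type> directed|undirected'", line_no
                )
            try:
                t = int(fields[1])
            except ValueError:
                raise GraphFileError(f"bad edge type {fields[1]!r}", line_no) from None
            if t in directedness:
                raise GraphFileError(f"edge type {t} declared twice", line_no)
            directedness[t] = fields[2] == "directed"
        elif kind == "V":
            if len(fields) < 3:
                raise GraphFileError("expected 'V <id> <label> ...'", line_no)
            vid, label = fields[1], fields[2]
            if vid in seen_ids:
                raise GraphFileError(f"duplicate vertex id {vid!r}", line_no)
            seen_ids.add(vid)
            possible: tuple[str, ...] = ()
            assigned: str | None = None
            for extra in fields[3:]:
                if extra.startswith("~"):
                    possible = tuple(a for a in extra[1:].split(",") if a)
                elif extra.startswith("="):
                    assigned = extra[1:]
                else:
                    raise GraphFileError(f"unrecognized field {extra!r}", line_no)
            vertices.append((vid, label, possible, assigned))
        elif kind == "E":
            if len(fields) != 4:
                raise GraphFileError("expected 'E <src> <dst> <type>'", line_no)
            try:
                t = int(fields[3])
            except ValueError:
                raise GraphFileError(f"bad edge type {fields[3]!r}", line_no) from None
            edges.append((fields[1], fields[2], t))
            edge_lines.append(line_no)
        else:
            raise GraphFileError(f"unknown record kind {kind!r}", line_no)
    if directedness and sorted(directedness) != list(range(len(directedness))):
        raise GraphFileError(
            f"edge types must be contiguous from 0, got {sorted(directedness)}"
        )
    directed = [directedness[t] for t in sorted(directedness)]
    kept: list[tuple[str, str, int]] = []
    for (u, v, t), line_no in zip(edges, edge_lines):
        if t not in directedness:
            raise GraphFileError(f"edge type {t} was never declared", line_no)
        if u == v:
            if t == HIERARCHY and directedness[t]:
                continue  # self-parent root declaration, normalized away
            raise GraphFileError(f"self-loop on {u!r} of type {t}", line_no)
        if u not in seen_ids or v not in seen_ids:
            missing = u if u not in seen_ids else v
            raise GraphFileError(f"edge references undeclared vertex {missing!r}", line_no)
        kept.append((u, v, t))
    try:
        return TypedGraph(
            [v[0] for v in vertices],
            {v[0]: v[1] for v in vertices},
            kept,
            directed,
            {v[0]: v[2] for v in vertices},
            {v[0]: v[3] for v in vertices},
        )
    except ValueError as exc:
        raise GraphFileError(str(exc)) from exc


def read_graph(path: PathLike) -> TypedGraph:
    with open(path, encoding="utf-8") as fh:
        return parse_graph(fh.read())


def format_graph(g: TypedGraph) -> str:
    lines = []
    for t, d in enumerate(g.directed):
        lines.append(f"T {t} {'directed' if d else 'undirected'}")
    for v in g.vertices:
        parts = ["V", v, g.labels[v]]
        if g.possible_attributes[v]:
            parts.append("~" + ",".join(g.possible_attributes[v]))
        if g.attributes[v] is not None:
            parts.append("=" + g.attributes[v])
        lines.append(" ".join(parts))
    for u, v, t in sorted(g.edges):
        lines.append(f"E {u} {v} {t}")
    return "\n".join(lines) + "\n"


def write_graph(g: TypedGraph, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(format_graph(g))


def parse_partition(text: str) -> OrderedPartition:
    cells = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        ids = [x.strip() for x in line.split(",") if x.strip()]
        if not ids:
            raise GraphFileError("empty cell", line_no)
        cells.append(ids)
    try:
        return OrderedPartition(cells)
    except ValueError as exc:
        raise GraphFileError(str(exc)) from exc


def read_partition(path: PathLike) -> OrderedPartition:
    with open(path, encoding="utf-8") as fh:
        return parse_partition(fh.read())


def format_partition(p: OrderedPartition) -> str:
    return "\n".join(",".join(sorted(cell)) for cell in p.cells) + "\n"


def write_partition(p: OrderedPartition, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(format_partition(p))
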