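"""Generalized equitable partition refinement and vertex individualization.

An ordered partition of the vertices of a typed graph is *generalized
equitable* when, for every edge type separately, any two vertices in the
same cell have the same number of edges of that type into every cell; for
directed types the outgoing and incoming counts are both required to match.
Restricted to a single undirected edge type this reduces to the classical
equitable-partition condition used by Nauty.

Every ordered partition has a unique coarsest generalized equitable
refinement (unique as an unordered partition; the cell order produced here
is fixed by a deterministic, isomorphism-invariant convention).  The
refinement is computed with a splitter worklist: a queue of "active" cells
is processed in FIFO order, each active cell splits the current cells by
edge counts into it, and fragments are ordered by their count key in
descending order — cells with higher degrees come before cells with lower
degrees — and appended to the queue.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Optional, Sequence

from .graph import IN, OUT, OrderedPartition, TypedGraph

__all__ = [
    "cell_degree_key",
    "is_generalized_equitable",
    "coarsest_equitable_refinement",
    "individualize",
    "individualize_and_refine",
]

# Cell-order conventions (fixed; see docs/methods.md).  Fragments produced
# by a splitter cell with more than one vertex are ordered by their count
# key descending (cells with higher degrees first); fragments produced by a
# singleton splitter are ordered ascending.  The worklist seeded after
# individualizing x is the new singleton {x}.
_MULTI_DESCENDING = True
_SINGLETON_DESCENDING = False
_SEED_COMPLEMENT = False


def _count_key(g: TypedGraph, v: str, target: frozenset) -> tuple[int, ...]:
    """Edge counts of ``v`` into ``target``, one block per edge type.

    Directed types contribute ``(out, in)``; undirected types a single
    incident count.  The flattened tuple (types in increasing index order)
    is the comparison key used to order split fragments.
    """
    m = g.num_edge_types
    out = [0] * m
    inc = [0] * m
    for nbr, e, kind in g.adjacency()[v]:
        if nbr in target:
            if kind == OUT:
                out[e] += 1
            else:
                inc[e] += 1
    key: list[int] = []
    for e in range(m):
        key.append(out[e])
        if g.directed[e]:
            key.append(inc[e])
    return tuple(key)


def cell_degree_key(
    g: TypedGraph, p: OrderedPartition, v: str
) -> tuple[tuple[int, ...], ...]:
    """Per-cell degree signature of ``v`` with respect to partition ``p``.

    Entry ``j`` is the :func:`_count_key` of ``v`` into the ``j``-th cell.
    Two vertices in the same cell of a generalized equitable partition have
    identical signatures; the signature is preserved by any isomorphism that
    maps one partition onto the other cell-by-cell.
    """
    return tuple(_count_key(g, v, cell) for cell in p.cells)


def is_generalized_equitable(g: TypedGraph, p: OrderedPartition) -> bool:
    """Check the generalized equitable condition cell by cell."""
    p.validate_over(g.vertices)
    for cell in p.cells:
        if len(cell) == 1:
            continue
        it = iter(cell)
        ref = cell_degree_key(g, p, next(it))
        if any(cell_degree_key(g, p, v) != ref for v in it):
            return False
    return True


def coarsest_equitable_refinement(
    g: TypedGraph,
    p: OrderedPartition,
    active: Optional[Iterable[frozenset]] = None,
) -> OrderedPartition:
    """Unique coarsest generalized equitable refinement of ``p``.

    ``active`` seeds the splitter worklist; by default every cell of ``p``
    is active (in partition order), which is correct for an arbitrary input
    partition.  During the canonical-labeling search, a partition obtained
    by individualizing ``x`` out of a cell ``C`` of an already-equitable
    partition only needs the new singleton ``{x}`` as seed: counts into the
    old cell ``C`` are constant on every cell of an equitable partition, so
    ``{x}`` and the remainder ``C \\ {x}`` induce exactly the same splits.
    """
    p.validate_over(g.vertices)
    cells: list[frozenset] = list(p.cells)
    queue: deque[frozenset] = deque(
        frozenset(c) for c in (p.cells if active is None else active)
    )
    adj = g.adjacency()
    n_singleton = sum(1 for c in cells if len(c) == 1)
    while queue and n_singleton < len(g.vertices):
        w = queue.popleft()
        # accumulate contributions of w into each incident vertex
        touched: dict[str, dict[tuple[int, int], int]] = {}
        for u in w:
            for nbr, e, kind in adj[u]:
                # flip perspective: an entry (nbr, e, IN) on u means nbr->u,
                # i.e. an outgoing edge of nbr into w
                slot = (e, OUT if kind == IN else (IN if g.directed[e] else OUT))
                d = touched.setdefault(nbr, {})
                d[slot] = d.get(slot, 0) + 1
        if not touched:
            continue
        m = g.num_edge_types
        new_cells: list[frozenset] = []
        for cell in cells:
            if len(cell) == 1 or not any(v in touched for v in cell):
                new_cells.append(cell)
                continue
            groups: dict[tuple[int, ...], list[str]] = {}
            for v in cell:
                counts = touched.get(v)
                key: list[int] = []
                for e in range(m):
                    key.append(0 if counts is None else counts.get((e, OUT), 0))
                    if g.directed[e]:
                        key.append(0 if counts is None else counts.get((e, IN), 0))
                groups.setdefault(tuple(key), []).append(v)
            if len(groups) == 1:
                new_cells.append(cell)
                continue
            descending = _MULTI_DESCENDING if len(w) > 1 else _SINGLETON_DESCENDING
            for key in sorted(groups, reverse=descending):
                frag = frozenset(groups[key])
                new_cells.append(frag)
                queue.append(frag)
                if len(frag) == 1:
                    n_singleton += 1
        cells = new_cells
    return OrderedPartition(cells)


def individualize(p: OrderedPartition, x: str) -> OrderedPartition:
    """Split ``x`` into its own cell, placed before the remainder.

    The cell ``C`` containing ``x`` is replaced by ``({x}, C \\ {x})``; all
    other cells are unchanged.  ``x`` must not already be in a singleton
    cell.
    """
    for i, cell in enumerate(p.cells):
        if x in cell:
            if len(cell) == 1:
                raise ValueError(f"vertex {x!r} is already in a singleton cell")
            rest = cell - {x}
            return OrderedPartition(
                p.cells[:i] + (frozenset({x}), rest) + p.cells[i + 1 :]
            )
    raise ValueError(f"vertex {x!r} not in partition")


def individualize_and_refine(
    g: TypedGraph, p: OrderedPartition, x: str
) -> OrderedPartition:
    """One downward step of the search tree: individualize ``x`` in the
    (equitable) partition ``p`` and re-refine, seeding the worklist with
    the new singleton cell ``{x}``."""
    q = individualize(p, x)
    if _SEED_COMPLEMENT:
        i = q.cells.index(frozenset({x}))
        seed = [q.cells[i + 1]]
    else:
        seed = [frozenset({x})]
    return coarsest_equitable_refinement(g, q, active=seed)
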