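"""Brute-force reference implementations for small graphs.

These enumerate vertex permutations explicitly and serve as the independent
ground truth against which the search-based canonical labeling is tested.
They respect vertex colors: only permutations that map every color class
(label + attribute signature) onto itself are considered, which is the
canonical-labeling problem actually solved for attributed molecular graphs.

All operations refuse graphs larger than a configurable budget (default 8
vertices); factorial enumeration beyond that is not the point of this
module.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .graph import TypedGraph

__all__ = ["OracleBudget", "brute_canonical", "brute_automorphisms"]


@dataclass(frozen=True)
class OracleBudget:
    max_vertices: int = 8


DEFAULT_BUDGET = OracleBudget()


def _check_budget(g: TypedGraph, budget: OracleBudget) -> None:
    if g.n > budget.max_vertices:
        raise ValueError(
            f"graph has {g.n} vertices, over the oracle budget of "
            f"{budget.max_vertices}"
        )


def _base_matrix(g: TypedGraph, order: tuple[str, ...]) -> np.ndarray:
    idx = {v: i for i, v in enumerate(order)}
    mat = np.zeros((g.n, g.n), dtype=np.uint8)
    for u, v, e in g.edges:
        mat[idx[u], idx[v]] += 1 << e
        if not g.directed[e]:
            mat[idx[v], idx[u]] += 1 << e
    return mat

def _color_blocks(g: TypedGraph) -> list[list[str]]:
    """Vertices grouped by color, classes in lexicographic color order."""
    groups: dict[tuple, list[str]] = {}
    for v in g.vertices:
        groups.setdefault(g.color_key(v), []).append(v)
    return [sorted(groups[k]) for k in sorted(groups)]


def _block_orderings(blocks: list[list[str]]):
    """All vertex orderings that keep each color class in its block."""
    for per_block in itertools.product(
        *(itertools.permutations(b) for b in blocks)
    ):
        yield tuple(v for block in per_block for v in block)


def brute_canonical(
    g: TypedGraph, budget: OracleBudget = DEFAULT_BUDGET, largest: bool = False
) -> str:
    """Extremal serialized adjacency string over color-preserving orderings.

    The row-major integer sequences of the permuted adjacency matrices are
    linearly ordered and the smallest is chosen as the canonical label
    (color classes stay in ascending key blocks, matching the reading used
    by the search-based labeler).  The result is invariant under any
    relabeling of ``g``.
    """
    _check_budget(g, budget)
    if g.n == 0:
        return ""
    blocks = _color_blocks(g)
    ref_order = tuple(v for b in blocks for v in b)
    mat = _base_matrix(g, ref_order)
    idx = {v: i for i, v in enumerate(ref_order)}
    best: bytes | None = None
    best_arr = None
    for ordering in _block_orderings(blocks):
        p = np.fromiter((idx[v] for v in ordering), dtype=np.intp, count=g.n)
        cand = mat[np.ix_(p, p)].tobytes()
        if best is None or (cand > best if largest else cand < best):
            best = cand
            best_arr = cand
    assert best_arr is not None
    return " ".join(str(b) for b in best_arr)


def brute_automorphisms(
    g: TypedGraph, budget: OracleBudget = DEFAULT_BUDGET
) -> list[dict[str, str]]:
    """All color- and edge-type-preserving permutations of the vertices.

    Each automorphism is returned as a mapping ``vertex -> image``.  The
    list always contains the identity and is closed under composition and
    inverse (it is the automorphism group).
    """
    _check_budget(g, budget)
    blocks = _color_blocks(g)
    ref_order = tuple(v for b in blocks for v in b)
    mat = _base_matrix(g, ref_order)
    idx = {v: i for i, v in enumerate(ref_order)}
    auts: list[dict[str, str]] = []
    for ordering in _block_orderings(blocks):
        # candidate permutation: ref_order[i] -> ordering[i]
        p = np.fromiter((idx[v] for v in ordering), dtype=np.intp, count=g.n)
        if np.array_equal(mat[np.ix_(p, p)], mat):
            # mat[p(i), p(j)] == mat[i, j] for all i, j means the map
            # ref_order[i] |-> ordering[i] preserves every typed edge
            auts.append({ref_order[i]: ordering[i] for i in range(g.n)})
    return auts
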