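"""Shared fixtures and small-graph builders for the test suite."""

import itertools
import random

import pytest

from hnauty import TypedGraph
from hnauty.fixtures import g1 as build_g1
from hnauty.fixtures import g2 as build_g2
from hnauty.fixtures import isomorphic_triple, lck_entity, lck_species, tcr_complex


def single_type_graph(n, pairs, labels=None):
    """Undirected single-edge-type graph on vertices v1..vn."""
    vs = [f"v{i}" for i in range(1, n + 1)]
    labels = labels or {v: "v" for v in vs}
    return TypedGraph(
        vs, labels, [(f"v{a}", f"v{b}", 0) for a, b in pairs], (False,)
    )


def all_single_type_graphs(n):
    """Every undirected single-type graph on exactly n labeled vertices."""
    pairs = list(itertools.combinations(range(1, n + 1), 2))
    for mask in range(1 << len(pairs)):
        yield single_type_graph(
            n, [pairs[k] for k in range(len(pairs)) if mask >> k & 1]
        )


def random_two_type_graph(rng, n, p_und=0.25, p_dir=0.25):
    """Random molecular-style graph: directed type 0, undirected type 1."""
    vs = [f"v{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            r = rng.random()
            if r < p_und:
                edges.append((vs[i], vs[j], 1))
            elif r < p_und + p_dir:
                if rng.random() < 0.5:
                    edges.append((vs[i], vs[j], 0))
                else:
                    edges.append((vs[j], vs[i], 0))
    return TypedGraph(vs, {v: "v" for v in vs}, edges, (True, False))


def relabeled_copy(g, seed):
    """A random isomorphic copy with both ids and stored order shuffled."""
    rng = random.Random(seed)
    images = list(g.vertices)
    rng.shuffle(images)
    order = list(images)
    rng.shuffle(order)
    return g.permuted(dict(zip(g.vertices, images)), new_order=order)


@pytest.fixture(scope="session")
def g1():
    return build_g1()


@pytest.fixture(scope="session")
def g2():
    return build_g2()


@pytest.fixture(scope="session")
def triple():
    return isomorphic_triple()


@pytest.fixture(scope="session")
def lck():
    return lck_species()


@pytest.fixture(scope="session")
def lck_entity_graph():
    return lck_entity()


@pytest.fixture(scope="session")
def tcr():
    return tcr_complex(expanded=False)


@pytest.fixture(scope="session")
def tcr_expanded():
    return tcr_complex(expanded=True)
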