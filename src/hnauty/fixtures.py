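"""Reference molecular graphs and small worked-example graphs.

* Lck — the Src-family tyrosine kinase, as a molecular entity graph (SH3,
  SH2 and PTK domains; tyrosines Y192, Y394, Y505 with U/P states) and as
  the chemical species graph in which Y505 is phosphorylated and bound
  intramolecularly to the SH2 domain.
* The TCR complex — a pseudo-hierarchy: the root complex contains the
  alpha-beta, gamma-epsilon, delta-epsilon and zeta-zeta dimers, chains
  carry linear motifs (ITAMs and the CD3-epsilon PRS), motifs carry
  tyrosines, and tyrosine Y188 of CD3-epsilon belongs to BOTH its PRS and
  its ITAM, so the containment relation is a DAG rather than a forest.
* ``g1``/``g2`` — two non-isomorphic 5-vertex graphs with identical degree
  sequences (complete bipartite on {v2,v4} vs {v1,v3,v5}; a 5-cycle with
  the chord v1-v3), the standard worked examples for equitable refinement.
* ``isomorphic_triple`` — a 4-cycle and two permuted copies of it, one
  produced by a non-automorphism (swap v3, v4) and one by an automorphism
  (swap v2, v4).

Greek letters are transliterated in vertex ids (alpha, beta, gamma, delta,
epsilon, zeta); ids are unique while labels follow the component names, so
e.g. the two zeta chains share the label ``zeta``.
"""

from __future__ import annotations

from .graph import HierarchicalMoleculeGraph, TypedGraph, build_graph

__all__ = [
    "LCK_COMPONENT_ORDER",
    "lck_entity",
    "lck_species",
    "tcr_complex",
    "g1",
    "g2",
    "isomorphic_triple",
    "CATALOG",
    "get_fixture",
]

#: The reference component order of the Lck species adjacency matrix.
LCK_COMPONENT_ORDER = ("Lck", "SH3", "SH2", "Y505", "PTK", "Y192", "Y394")

_MOLECULE_TYPES = ("directed", "undirected")  # hierarchy, bond

_LCK_VERTICES = [
    ("Lck", "Lck"),
    ("SH3", "SH3"),
    ("SH2", "SH2"),
    ("Y505", "Y505", ("U", "P")),
    ("PTK", "PTK"),
    ("Y192", "Y192", ("U", "P")),
    ("Y394", "Y394", ("U", "P")),
]

_LCK_HIERARCHY = [
    ("Lck", "SH3", 0),
    ("Lck", "SH2", 0),
    ("Lck", "Y505", 0),
    ("Lck", "PTK", 0),
    ("SH2", "Y192", 0),
    ("PTK", "Y394", 0),
]


def lck_entity() -> HierarchicalMoleculeGraph:
    """Lck as a molecular entity graph: the strict domain hierarchy with
    unassigned phosphorylation states and no bonds."""
    g = build_graph(_LCK_VERTICES, _LCK_HIERARCHY, _MOLECULE_TYPES)
    return HierarchicalMoleculeGraph(g, flavor="entity")


def lck_species() -> HierarchicalMoleculeGraph:
    """The Lck chemical species graph: Y192 and Y394 unphosphorylated,
    Y505 phosphorylated and bound intramolecularly to the SH2 domain
    (one undirected bond edge SH2–Y505)."""
    vertices = []
    states = {"Y192": "U", "Y394": "U", "Y505": "P"}
    for spec in _LCK_VERTICES:
        if spec[0] in states:
            vertices.append((spec[0], spec[1], spec[2], states[spec[0]]))
        else:
            vertices.append(spec)
    edges = _LCK_HIERARCHY + [("SH2", "Y505", 1)]
    g = build_graph(vertices, edges, _MOLECULE_TYPES)
    return HierarchicalMoleculeGraph(g, flavor="species")


def _itam(vertices, edges, parent: str, name: str, shared_y: str | None = None):
    """Attach an ITAM with two tyrosines under ``parent``; if ``shared_y``
    is given it is used as the id of the first tyrosine (already declared
    elsewhere) instead of creating a fresh one."""
    vertices.append((name, "ITAM"))
    edges.append((parent, name, 0))
    if shared_y is None:
        vertices.append((f"{name}_Y1", "Y", ("U", "P")))
        edges.append((name, f"{name}_Y1", 0))
    else:
        edges.append((name, shared_y, 0))
    vertices.append((f"{name}_Y2", "Y", ("U", "P")))
    edges.append((name, f"{name}_Y2", 0))


def _epsilon_chain(vertices, edges, chain: str):
    """CD3-epsilon internals: a PRS and an ITAM overlapping at Y188."""
    y188 = f"{chain}_Y188"
    vertices.append((f"{chain}_PRS", "PRS"))
    edges.append((chain, f"{chain}_PRS", 0))
    vertices.append((y188, "Y188", ("U", "P")))
    edges.append((f"{chain}_PRS", y188, 0))
    _itam(vertices, edges, chain, f"{chain}_ITAM", shared_y=y188)


def tcr_complex(expanded: bool = False) -> HierarchicalMoleculeGraph:
    """The T cell receptor complex as a pseudo-hierarchical entity graph.

    ``expanded=False`` mirrors the usual drawing in which only one
    representative polypeptide chain per dimer is developed beyond the
    component-molecules level; ``expanded=True`` develops all eight chains
    (both CD3-epsilon chains with their overlapping PRS/ITAM, three ITAMs
    on each zeta chain) and adds the intradimer disulfide links as bond
    edges.  In both variants Y188 of CD3-epsilon has two hierarchy parents
    (its PRS and its ITAM), making the graph a DAG rather than a forest.
    """
    vertices: list[tuple] = [("TCR", "TCR")]
    edges: list[tuple[str, str, int]] = []
    for dimer in ("alphabeta", "gammaepsilon", "deltaepsilon", "zetazeta"):
        vertices.append((dimer, dimer))
        edges.append(("TCR", dimer, 0))

    def chain(dimer: str, cid: str, label: str):
        vertices.append((cid, label))
        edges.append((dimer, cid, 0))

    if not expanded:
        chain("alphabeta", "alpha", "alpha")
        chain("gammaepsilon", "epsilon", "epsilon")
        chain("deltaepsilon", "delta", "delta")
        chain("zetazeta", "zeta", "zeta")
        _epsilon_chain(vertices, edges, "epsilon")
        _itam(vertices, edges, "delta", "delta_ITAM")
        for k in (1, 2, 3):
            _itam(vertices, edges, "zeta", f"zeta_ITAM{k}")
    else:
        chain("alphabeta", "alpha", "alpha")
        chain("alphabeta", "beta", "beta")
        chain("gammaepsilon", "gamma", "gamma")
        chain("gammaepsilon", "epsilon1", "epsilon")
        chain("deltaepsilon", "delta", "delta")
        chain("deltaepsilon", "epsilon2", "epsilon")
        chain("zetazeta", "zeta1", "zeta")
        chain("zetazeta", "zeta2", "zeta")
        _itam(vertices, edges, "gamma", "gamma_ITAM")
        _itam(vertices, edges, "delta", "delta_ITAM")
        _epsilon_chain(vertices, edges, "epsilon1")
        _epsilon_chain(vertices, edges, "epsilon2")
        for z in ("zeta1", "zeta2"):
            for k in (1, 2, 3):
                _itam(vertices, edges, z, f"{z}_ITAM{k}")
        # intradimer disulfide links, represented as bond edges
        edges += [
            ("alpha", "beta", 1),
            ("gamma", "epsilon1", 1),
            ("delta", "epsilon2", 1),
            ("zeta1", "zeta2", 1),
        ]
    g = build_graph(vertices, edges, _MOLECULE_TYPES)
    return HierarchicalMoleculeGraph(g, flavor="entity")


def _single_type(pairs) -> TypedGraph:
    vs = [f"v{i}" for i in range(1, 6)]
    return TypedGraph(
        vs,
        {v: "v" for v in vs},
        [(f"v{a}", f"v{b}", 0) for a, b in pairs],
        (False,),
    )


def g1() -> TypedGraph:
    """Five vertices, edges between v_i and v_j whenever i - j is odd:
    the complete bipartite graph on {v2, v4} against {v1, v3, v5}."""
    return _single_type(
        (i, j) for i in range(1, 6) for j in range(i + 1, 6) if (i - j) % 2 == 1
    )


def g2() -> TypedGraph:
    """The 5-cycle v1-v2-v3-v4-v5-v1 with the extra chord v1-v3."""
    return _single_type([(1, 2), (2, 3), (3, 4), (4, 5), (5, 1), (1, 3)])


def isomorphic_triple() -> tuple[TypedGraph, TypedGraph, TypedGraph]:
    """A 4-cycle and two isomorphic copies of it.

    The second graph applies the permutation swapping v3 and v4 (not an
    automorphism of the cycle), the third the permutation swapping v2 and
    v4 (an automorphism), so all three are isomorphic but only the third
    has the same edge set as the first.
    """
    vs = ["v1", "v2", "v3", "v4"]
    base = TypedGraph(
        vs,
        {v: "v" for v in vs},
        [("v1", "v2", 0), ("v2", "v3", 0), ("v3", "v4", 0), ("v4", "v1", 0)],
        (False,),
    )
    pi1 = {"v1": "v1", "v2": "v2", "v3": "v4", "v4": "v3"}
    pi2 = {"v1": "v1", "v2": "v4", "v3": "v3", "v4": "v2"}
    return base, base.permuted(pi1, new_order=vs), base.permuted(pi2, new_order=vs)


CATALOG = {
    "lck_entity": lambda: lck_entity().underlying,
    "lck_species": lambda: lck_species().underlying,
    "tcr": lambda: tcr_complex(expanded=False).underlying,
    "tcr_expanded": lambda: tcr_complex(expanded=True).underlying,
    "g1": g1,
    "g2": g2,
    "iso_triple_1": lambda: isomorphic_triple()[0],
    "iso_triple_2": lambda: isomorphic_triple()[1],
    "iso_triple_3": lambda: isomorphic_triple()[2],
}


def get_fixture(name: str) -> TypedGraph:
    try:
        return CATALOG[name]()
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(CATALOG))}"
        ) from None
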