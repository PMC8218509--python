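"""Absorption edges, D_A, SCC condensation, and the out-forest selection."""

import itertools
import random

import networkx as nx
import pytest

from esskit import greedy_path_cover
from esskit.absorption import (
    AbsorptionDigraph,
    AbsorptionEdge,
    build_absorption_digraph,
    condensation,
    find_absorption_edges,
    max_edge_spanning_out_forest,
)
from esskit.bidigraph import build_dbg, compact

from conftest import brute_force_max_out_forest, noisy_kmer_set, random_kmer_set


def _digraph(n, arcs):
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u, v in arcs:
        g.add_edge(u, v, edge=None)
    return AbsorptionDigraph(graph=g)


# ---------------------------------------------------------------------------
# find_absorption_edges on real graphs


def test_toy_absorb_finds_exactly_one_edge(fixtures):
    f = fixtures["toy_absorb"]
    edges = find_absorption_edges(f.graph, f.cover)
    assert len(edges) == 1
    (ae,) = edges
    assert ae.parent_vertex == "ACG" and ae.child_vertex == "GTA"
    assert f.cover.is_internal(ae.parent_vertex)
    assert not f.cover.is_internal(ae.child_vertex)


def test_absorption_requires_internal_parent_and_endpoint_child():
    for seed in range(15):
        K = random_kmer_set(seed)
        if K is None:
            continue
        cg = compact(build_dbg(K))
        cover = greedy_path_cover(cg)
        for ae in find_absorption_edges(cg, cover):
            assert cover.path_of(ae.parent_vertex) != cover.path_of(ae.child_vertex)
            assert cover.is_internal(ae.parent_vertex)
            assert ae.child_side in cover.free_sides(ae.child_vertex)


def test_self_absorption_rejected():
    with pytest.raises(ValueError):
        AbsorptionEdge(0, 0, "A" * 5, "C" * 5, 0, 1, frozenset())


# ---------------------------------------------------------------------------
# digraph construction and condensation


def test_digraph_is_simple_with_deterministic_representative(fixtures):
    f = fixtures["mutual_cycle"]
    cg = compact(f.graph)
    cover = greedy_path_cover(cg)
    edges = find_absorption_edges(cg, cover)
    da = build_absorption_digraph(edges, cover)
    # simple: one arc per ordered pair, representative is the smallest edge
    for (p, c) in da.graph.edges:
        reps = [e for e in edges if (e.parent_path, e.child_path) == (p, c)]
        assert da.arc_edge(p, c) == min(reps)
    # the frozen fixture really contains a 2-cycle
    assert any(da.graph.has_edge(v, u) for u, v in da.graph.edges if u != v)


def test_condensation_examples():
    d = _digraph(3, [(0, 1), (1, 0), (0, 2)])
    comps, n_sc = condensation(d)
    assert sorted(map(sorted, comps)) == [[0, 1], [2]]
    assert n_sc == 1

    comps, n_sc = condensation(_digraph(3, []))
    assert len(comps) == 3 and n_sc == 3

    comps, n_sc = condensation(_digraph(3, [(0, 1), (1, 2), (2, 0)]))
    assert len(comps) == 1 and n_sc == 1


# ---------------------------------------------------------------------------
# out-forest selection (checked against brute force)


def _check_forest(d: AbsorptionDigraph):
    forest = max_edge_spanning_out_forest(d)
    nodes = d.nodes
    arcs = set(d.graph.edges)
    # structural: spanning, in-degree <= 1, acyclic, arcs drawn from D_A
    assert set(forest.roots) | set(forest.parent_of) == set(nodes)
    assert not set(forest.roots) & set(forest.parent_of)
    for c, (p, _) in forest.parent_of.items():
        assert (p, c) in arcs
    seen = set()
    for c in forest.parent_of:
        chain = set()
        while c in forest.parent_of:
            assert c not in chain
            chain.add(c)
            c = forest.parent_of[c][0]
    # optimality vs brute force
    best_edges, min_trees = brute_force_max_out_forest(nodes, arcs)
    assert forest.n_arcs == best_edges
    assert len(forest.roots) == min_trees
    _, n_sc = condensation(d)
    assert len(forest.roots) == n_sc
    return forest


def test_forest_examples():
    f = _check_forest(_digraph(3, [(0, 1), (1, 0), (0, 2)]))
    assert len(f.roots) == 1 and f.n_arcs == 2
    f = _check_forest(_digraph(3, []))
    assert len(f.roots) == 3 and f.n_arcs == 0
    f = _check_forest(_digraph(3, [(0, 1), (1, 2), (2, 0)]))
    assert len(f.roots) == 1 and f.n_arcs == 2


def test_forest_exhaustive_small_digraphs():
    """Every labeled digraph on up to 4 nodes, no self-loops."""
    for n in range(1, 5):
        pairs = [(u, v) for u in range(n) for v in range(n) if u != v]
        for mask in range(1 << len(pairs)):
            arcs = [p for i, p in enumerate(pairs) if mask >> i & 1]
            _check_forest(_digraph(n, arcs))


@pytest.mark.parametrize("seed", range(200))
def test_forest_random_digraphs(seed):
    rng = random.Random(seed)
    n = rng.randrange(5, 9)
    pairs = [(u, v) for u in range(n) for v in range(n) if u != v]
    arcs = [p for p in pairs if rng.random() < 0.25]
    d = _digraph(n, arcs)
    # keep the oracle tractable
    prod = 1
    for v in range(n):
        prod *= 1 + sum(1 for (a, b) in arcs if b == v)
    if prod > 2_000_000:
        pytest.skip("oracle too large for this draw")
    _check_forest(d)


def test_forest_is_deterministic():
    d = _digraph(6, [(0, 1), (1, 0), (2, 3), (3, 4), (0, 5), (5, 2)])
    f1 = max_edge_spanning_out_forest(d)
    f2 = max_edge_spanning_out_forest(d)
    assert f1.parent_of.keys() == f2.parent_of.keys()
    assert f1.roots == f2.roots
    assert all(f1.parent_of[c][0] == f2.parent_of[c][0] for c in f1.parent_of)


def test_nsc_at_least_components_on_real_graphs():
    """The source-component count never drops below the graph's component count."""
    from esskit.pathcover import cover_lower_bound

    for seed in range(8):
        K = noisy_kmer_set(seed, k=11, genome_length=600)
        cg = compact(build_dbg(K))
        cover = greedy_path_cover(cg)
        da = build_absorption_digraph(find_absorption_edges(cg, cover), cover)
        _, n_sc = condensation(da)
        assert n_sc >= cover_lower_bound(cg).C
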