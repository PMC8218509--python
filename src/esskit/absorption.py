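"""Absorption edges, the absorption digraph, and its edge-maximizing out-forest.

An *absorption edge* is a cdBG edge joining an internal vertex of one cover
path (the parent) to an endpoint vertex of another (the child), attaching at
the child occurrence's outer free side, so the child path can be rewritten
with its redundant (k-1)-mer replaced by a marker and spliced into the parent.

The absorption digraph D_A has one node per cover path and one arc per ordered
(parent, child) pair. To absorb as many paths as possible without cycles, we
select a spanning out-forest with the maximum number of arcs: decompose D_A
into strongly connected components, pick one starter node per *source*
component, and run DFS initiating every new tree from a starter. The forest
then has exactly n_sc trees (the number of source components), the minimum
possible, hence the maximum number of arcs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .bidigraph import BidirectedDNAGraph, Edge, _edge_pairs, is_loop
from .pathcover import PathCover


@dataclass(frozen=True, order=True)
class AbsorptionEdge:
    """One admissible absorption: parent path internal vertex -> child path endpoint."""

    parent_path: int
    child_path: int
    parent_vertex: str
    child_vertex: str
    parent_side: int
    child_side: int
    cdbg_edge: Edge = field(compare=False)

    def __post_init__(self) -> None:
        if self.parent_path == self.child_path:
            raise ValueError("absorption requires two distinct paths")


def _child_attachment_ok(cover: PathCover, v: str, side: int) -> bool:
    """Can the child path be flipped so ``v`` is its initiator with outer side ``side``?

    The edge must attach at the outer (free) side of the endpoint occurrence;
    attaching at the side consumed by the child path's first internal edge
    cannot be encoded (the shared (k-1)-mer lies interior to the spelling).
    """
    return side in cover.free_sides(v)


def find_absorption_edges(
    cdbg: BidirectedDNAGraph, cover: PathCover, *, require_internal_parent: bool = True
) -> list[AbsorptionEdge]:
    """Every cdBG edge admissible as an absorption, in deterministic order.

    ``require_internal_parent=False`` relaxes the internal-parent condition
    (used by the tip-mode variant, where parents are never themselves absorbed).
    """
    out: list[AbsorptionEdge] = []
    for e in sorted(cdbg.edges, key=lambda e: tuple(sorted(e))):
        if is_loop(e):
            continue
        pairs = _edge_pairs(e)
        for (pv, ps), (cv, cs) in (pairs, pairs[::-1]):
            pp, cp = cover.path_of(pv), cover.path_of(cv)
            if pp == cp:
                continue
            if require_internal_parent and not cover.is_internal(pv):
                continue
            if not _child_attachment_ok(cover, cv, cs):
                continue
            out.append(
                AbsorptionEdge(
                    parent_path=pp,
                    child_path=cp,
                    parent_vertex=pv,
                    child_vertex=cv,
                    parent_side=ps,
                    child_side=cs,
                    cdbg_edge=e,
                )
            )
    out.sort()
    return out


@dataclass
class AbsorptionDigraph:
    """Simple digraph over path ids; each arc carries one representative edge."""

    graph: nx.DiGraph

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    def arc_edge(self, parent: int, child: int) -> AbsorptionEdge:
        return self.graph.edges[parent, child]["edge"]


def build_absorption_digraph(
    edges: Iterable[AbsorptionEdge], cover: PathCover
) -> AbsorptionDigraph:
    """One arc per ordered (parent, child) pair, deduplicated deterministically.

    When several absorption edges join the same pair, the lexicographically
    smallest (parent_vertex, child_vertex, sides) representative is kept.
    """
    g = nx.DiGraph()
    g.add_nodes_from(range(len(cover)))
    for ae in sorted(edges):
        key = (ae.parent_path, ae.child_path)
        if not g.has_edge(*key):
            g.add_edge(*key, edge=ae)
    return AbsorptionDigraph(graph=g)


def condensation(d: AbsorptionDigraph) -> tuple[list[set[int]], int]:
    """Strongly connected components and the number of source components n_sc."""
    cond = nx.condensation(d.graph)
    comps = [set(cond.nodes[c]["members"]) for c in sorted(cond.nodes)]
    n_sc = sum(1 for c in cond.nodes if cond.in_degree(c) == 0)
    return comps, n_sc


@dataclass(frozen=True)
class OutForest:
    """A spanning out-forest of D_A: parent assignment for absorbed paths."""

    parent_of: dict[int, tuple[int, AbsorptionEdge]]
    roots: tuple[int, ...]

    @property
    def n_arcs(self) -> int:
        return len(self.parent_of)

    def children_of(self, pid: int) -> list[tuple[int, AbsorptionEdge]]:
        return sorted(
            (c, ae) for c, (p, ae) in self.parent_of.items() if p == pid
        )


def max_edge_spanning_out_forest(d: AbsorptionDigraph) -> OutForest:
    """DFS forest started from one starter per source SCC: n_sc trees, max arcs.

    Starter within a source component: its smallest path id. DFS neighbor
    order: sorted child path id. Deterministic.
    """
    g = d.graph
    cond = nx.condensation(g)
    starters = sorted(
        min(cond.nodes[c]["members"]) for c in cond.nodes if cond.in_degree(c) == 0
    )
    visited: set[int] = set()
    parent_of: dict[int, tuple[int, AbsorptionEdge]] = {}
    roots: list[int] = []

    def dfs(root: int) -> None:
        visited.add(root)
        stack = [(root, iter(sorted(g.successors(root))))]
        while stack:
            node, it = stack[-1]
            for nxt in it:
                if nxt not in visited:
                    visited.add(nxt)
                    parent_of[nxt] = (node, g.edges[node, nxt]["edge"])
                    stack.append((nxt, iter(sorted(g.successors(nxt)))))
                    break
            else:
                stack.pop()

    for s in starters:
        if s not in visited:  # distinct source components are mutually unreachable
            roots.append(s)
            dfs(s)
    for v in sorted(g.nodes):  # pragma: no cover - every node is starter-reachable
        if v not in visited:
            roots.append(v)
            dfs(v)
    return OutForest(parent_of=parent_of, roots=tuple(roots))


def forest_to_dot(d: AbsorptionDigraph, f: OutForest) -> str:
    """DOT dump of D_A with the chosen forest arcs highlighted (debug aid)."""
    lines = ["digraph absorption {"]
    for n in d.nodes:
        shape = "doublecircle" if n in f.roots else "circle"
        lines.append(f'  p{n} [shape={shape}];')
    in_forest = {(p, c) for c, (p, _) in f.parent_of.items()}
    for p, c in sorted(d.graph.edges):
        style = "bold" if (p, c) in in_forest else "dashed"
        lines.append(f"  p{p} -> p{c} [style={style}];")
    lines.append("}")
    return "\n".join(lines) + "\n"
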