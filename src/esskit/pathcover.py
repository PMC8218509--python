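"""Vertex-disjoint path covers of the compacted graph and their string sets.

A path cover Psi of cdBG(K) spells a spectrum-preserving string set (SPSS) of
weight |K| + |Psi|*(k-1): every merge along a cover edge removes one duplicate
(k-1)-mer. The greedy cover here scans edges in a fixed lexicographic order and
merges two distinct paths whenever the edge joins currently-free outer endpoint
sides of both (union-find prevents cycles), which is deterministic and, like
the usual greedy covers in this field, lands within a few percent of optimal.

Lower bounds: ``beta`` from the dead-end-side argument (every edge-free vertex
side must be a path-endpoint side and each path exposes two; each connected
component needs at least one path) and ``C``, the number of connected
components of the underlying undirected graph. Any enriched-string
representation built on absorptions weighs at least |K| + 3*beta + C*(k-4)
(valid for k > 4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .bidigraph import (
    BidirectedDNAGraph,
    Edge,
    OrientedPath,
    _edge_key,
    _edge_pairs,
    is_loop,
    spell_path,
)
from .errors import GraphError, SpssViolationError
from .kmerset import canonicalize


@dataclass(frozen=True)
class SPSS:
    """A spectrum-preserving string set: strings of length >= k, k-mers exactly K."""

    strings: tuple[str, ...]
    k: int


def weight(strings: Iterable[str]) -> int:
    """Total character count of a string collection."""
    return sum(len(x) for x in strings)


class PathCover:
    """A set of vertex-disjoint oriented paths covering every vertex exactly once.

    Path ids are indices into ``paths``, which is sorted by spelling, so ids
    are deterministic for a given graph and cover.
    """

    def __init__(self, paths: Iterable[OrientedPath], graph: BidirectedDNAGraph):
        self.graph = graph
        self.paths: tuple[OrientedPath, ...] = tuple(
            sorted(paths, key=lambda p: graph.spell(p))
        )
        self._locate: dict[str, tuple[int, int]] = {}
        for pid, p in enumerate(self.paths):
            graph.check_path(p)
            for pos, (v, _) in enumerate(p.steps):
                if v in self._locate:
                    raise GraphError(f"vertex {v!r} appears in two cover paths")
                self._locate[v] = (pid, pos)
        if set(self._locate) != set(graph.vertices):
            missing = set(graph.vertices) - set(self._locate)
            raise GraphError(f"cover misses vertices: {sorted(missing)[:3]}...")

    def __len__(self) -> int:
        return len(self.paths)

    def __iter__(self):
        return iter(self.paths)

    def path_of(self, v: str) -> int:
        return self._locate[v][0]

    def position_of(self, v: str) -> tuple[int, int]:
        """(path-id, position along the path) of vertex ``v``."""
        return self._locate[v]

    def is_internal(self, v: str) -> bool:
        pid, pos = self._locate[v]
        return 0 < pos < len(self.paths[pid]) - 1

    def free_sides(self, v: str) -> tuple[int, ...]:
        """Outer (path-endpoint) sides of ``v`` not consumed by cover edges."""
        pid, pos = self._locate[v]
        p = self.paths[pid]
        if len(p) == 1:
            return (0, 1)
        if pos == 0:
            return (p.steps[0][1],)  # entry side of the first occurrence
        if pos == len(p) - 1:
            return (1 - p.steps[-1][1],)  # exit side of the last occurrence
        return ()


def greedy_path_cover(cdbg: BidirectedDNAGraph) -> PathCover:
    """Greedy vertex-disjoint path cover, scanning edges in sorted order."""
    parent: dict[str, str] = {v: v for v in cdbg.vertices}

    def find(v: str) -> str:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    # (vertex, side) -> True while it is a free outer endpoint side.
    free: set[tuple[str, int]] = {(v, s) for v in cdbg.vertices for s in (0, 1)}
    chosen: dict[tuple[str, int], Edge] = {}

    for e in sorted(cdbg.edges, key=_edge_key):
        if is_loop(e):
            continue
        (a, sa), (b, sb) = sorted(e)
        if (a, sa) in free and (b, sb) in free and find(a) != find(b):
            parent[find(a)] = find(b)
            free.discard((a, sa))
            free.discard((b, sb))
            chosen[(a, sa)] = e
            chosen[(b, sb)] = e

    # Rebuild oriented paths by walking the chosen edges.
    visited: set[str] = set()
    paths: list[OrientedPath] = []
    for v in sorted(cdbg.vertices):
        if v in visited:
            continue
        steps = _walk_cover_chain(v, chosen)
        p = OrientedPath(tuple(steps))
        p = _flip_normalize(p, cdbg)
        paths.append(p)
        visited.update(p.vertices)
    return PathCover(paths, cdbg)


def _walk_cover_chain(
    v: str, chosen: dict[tuple[str, int], Edge]
) -> list[tuple[str, int]]:
    """Walk the chain of chosen cover edges through ``v`` end to end."""

    def walk(start: tuple[str, int]) -> list[tuple[str, int]]:
        steps = [start]
        cur, o = start
        while True:
            e = chosen.get((cur, 1 - o))
            if e is None:
                return steps
            (x, sx), (y, sy) = _edge_pairs(e)
            nxt, entry = (y, sy) if (x, sx) == (cur, 1 - o) else (x, sx)
            steps.append((nxt, entry))
            cur, o = nxt, entry

    first_leg = walk((v, 1))
    end_v, end_o = first_leg[-1]
    return walk((end_v, 1 - end_o))


def _flip_normalize(p: OrientedPath, g: BidirectedDNAGraph) -> OrientedPath:
    """Deterministic direction: smaller (first label, spelling) wins."""
    q = p.flipped()
    return min(p, q, key=lambda r: (r.steps[0][0], g.spell(r), r.steps))


def spell_cover(cover: PathCover, cdbg: BidirectedDNAGraph | None = None) -> SPSS:
    """Spell every cover path; asserts the exact cover weight identity.

    weight == |K| + |Psi|*(k-1), and no k-mer is duplicated across spellings.
    """
    g = cdbg if cdbg is not None else cover.graph
    strings = tuple(spell_path(p, g)[0] for p in cover.paths)
    k = g.k
    expected = g.num_kmers() + len(cover.paths) * (k - 1)
    got = weight(strings)
    if got != expected:
        raise GraphError(
            f"cover weight identity violated: weight {got} != |K| + |Psi|(k-1) = {expected}"
        )
    seen: set[str] = set()
    for s in strings:
        for i in range(len(s) - k + 1):
            x = canonicalize(s[i : i + k])
            if x in seen:
                raise SpssViolationError(f"duplicate k-mer {x!r} across cover spellings")
            seen.add(x)
    return SPSS(strings=strings, k=k)


@dataclass(frozen=True)
class CoverBound:
    """Lower bounds: beta on |Psi| over all covers, C connected components."""

    beta: int
    C: int


def cover_lower_bound(cdbg: BidirectedDNAGraph) -> CoverBound:
    """Dead-end-side bound beta and component count C of the underlying graph."""
    ug = nx.Graph()
    ug.add_nodes_from(cdbg.vertices)
    for e in cdbg.edges:
        if not is_loop(e):
            (u, _), (v, _) = sorted(e)
            ug.add_edge(u, v)
    beta = 0
    C = 0
    for comp in nx.connected_components(ug):
        C += 1
        dead_sides = sum(len(cdbg.dead_end_sides(v)) for v in comp)
        beta += max(1, -(-dead_sides // 2))  # ceil
    return CoverBound(beta=beta, C=C)


def ess_weight_lower_bound(num_kmers: int, bound: CoverBound, k: int) -> int:
    """|K| + 3*beta + C*(k-4): the floor for absorption-based representations (k > 4)."""
    if k < 3:
        raise ValueError(f"k must be >= 3, got {k}")
    return num_kmers + 3 * bound.beta + bound.C * (k - 4)
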