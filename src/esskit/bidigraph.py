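"""Bidirected DNA graphs: de Bruijn construction, spelling, unitigs, compaction.

Every vertex has two *sides* (0 and 1) and carries a canonical DNA label of
length >= k. An edge is an unordered set of two (vertex, side) pairs and exists
exactly when the two labels have the corresponding oriented (k-1)-overlap:
``suf(orient(lab(u0), 1-s0)) == pre(orient(lab(u1), s1))`` where suf/pre take
the last/first k-1 characters.

Orientation convention (used consistently by paths, the cover, and the
encoder): an occurrence of vertex ``u`` with orientation flag ``o`` is
``orient(lab(u), o)``; the occurrence *enters* through side ``o`` (its front)
and *exits* through side ``1-o`` (its back). Under this convention a path step
sequence ((u0,o0),...,(un,on)) uses, between consecutive steps, the edge
``{(u_{i-1}, 1-o_{i-1}), (u_i, o_i)}``, and consecutive oriented occurrences
overlap by exactly k-1 characters, so the path spells a single DNA string.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import GraphError
from .kmerset import CanonicalKmerSet, canonicalize, reverse_complement

# An edge is a frozenset of (vertex, side) pairs. A palindromic self-overlap
# loop {(u,s),(u,s)} collapses to a singleton frozenset and is kept once.
Edge = frozenset


def orient(x: str, s: int) -> str:
    """``x`` if s == 0, its reverse complement if s == 1."""
    if s not in (0, 1):
        raise ValueError(f"orientation flag must be 0 or 1, got {s}")
    return x if s == 0 else reverse_complement(x)


def oriented_overlap(x0: str, s0: int, x1: str, s1: int, k: int) -> bool:
    """True iff x0 and x1 have an (s0, s1)-oriented (k-1)-overlap.

    Symmetric under swapping the two (string, side) pairs.
    """
    return orient(x0, 1 - s0)[-(k - 1) :] == orient(x1, s1)[: k - 1]


def glue(x: str, y: str, k: int) -> str:
    """Concatenate x and y overlapping by k-1 characters (suf(x) must equal pre(y))."""
    if x[-(k - 1) :] != y[: k - 1]:
        raise GraphError(f"cannot glue: suffix {x[-(k-1):]!r} != prefix {y[:k-1]!r}")
    return x + y[k - 1 :]


def _side_word(label: str, s: int, k: int) -> str:
    """The outgoing junction (k-1)-mer at side ``s``: suf(orient(label, 1-s))."""
    return orient(label, 1 - s)[-(k - 1) :]


@dataclass(frozen=True)
class OrientedPath:
    """A vertex-disjoint oriented path: steps of (vertex-id, orientation flag)."""

    steps: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise GraphError("a path must have at least one step")
        vertices = [v for v, _ in self.steps]
        if len(set(vertices)) != len(vertices):
            raise GraphError("path revisits a vertex")

    @property
    def vertices(self) -> tuple[str, ...]:
        return tuple(v for v, _ in self.steps)

    def flipped(self) -> "OrientedPath":
        """Reverse the step order and flip every orientation (RC of the spelling)."""
        return OrientedPath(tuple((v, 1 - o) for v, o in reversed(self.steps)))

    def __len__(self) -> int:
        return len(self.steps)


class BidirectedDNAGraph:
    """Overlap-closed bidirected DNA graph over canonical labels.

    Vertex ids are the canonical labels themselves (content-addressed), which
    makes every downstream ordering deterministic without seeds.
    """

    def __init__(self, labels: Iterable[str], k: int, edges: Iterable[Edge] | None = None):
        self.k = k
        self.vertices: frozenset[str] = frozenset(labels)
        if not self.vertices:
            raise GraphError("graph must have at least one vertex")
        for v in self.vertices:
            if len(v) < k:
                raise GraphError(f"label {v!r} shorter than k={k}")
            if canonicalize(v) != v:
                raise GraphError(f"label {v!r} is not canonical")
        if edges is None:
            self.edges = self._overlap_closure()
        else:
            self.edges = frozenset(edges)
        self._adj: dict[tuple[str, int], list[Edge]] = defaultdict(list)
        for e in sorted(self.edges, key=_edge_key):
            for vs in _edge_pairs(e):
                self._adj[vs].append(e)

    # -- construction -------------------------------------------------------

    def _overlap_closure(self) -> frozenset:
        """One edge for every oriented (k-1)-overlap between labels (loops included)."""
        k = self.k
        buckets: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
        for v in self.vertices:
            for s in (0, 1):
                w = _side_word(v, s, k)
                buckets[canonicalize(w)].append((v, s, w))
        edges = set()
        for group in buckets.values():
            for i, (v0, s0, w0) in enumerate(group):
                rc0 = reverse_complement(w0)
                for v1, s1, w1 in group[i:]:
                    if w1 == rc0:
                        edges.add(frozenset({(v0, s0), (v1, s1)}))
        return frozenset(edges)

    # -- basic queries -------------------------------------------------------

    def lab(self, v: str) -> str:
        if v not in self.vertices:
            raise GraphError(f"unknown vertex {v!r}")
        return v

    def incident(self, v: str, s: int) -> list[Edge]:
        """Edges incident to side ``s`` of vertex ``v`` (deterministic order)."""
        self.lab(v)
        return self._adj.get((v, s), [])

    def dead_end_sides(self, v: str) -> set[int]:
        """Sides of ``v`` with no incident edges; dead-end iff exactly one side."""
        self.lab(v)
        return {s for s in (0, 1) if not self._adj.get((v, s))}

    def is_dead_end(self, v: str) -> bool:
        return len(self.dead_end_sides(v)) == 1

    def num_kmers(self) -> int:
        return sum(len(v) - self.k + 1 for v in self.vertices)

    # -- paths ---------------------------------------------------------------

    def step_edge(self, a: tuple[str, int], b: tuple[str, int]) -> Edge:
        """The edge used between consecutive oriented steps a -> b."""
        e = frozenset({(a[0], 1 - a[1]), (b[0], b[1])})
        if e not in self.edges:
            raise GraphError(f"no edge between oriented steps {a} and {b}")
        return e

    def check_path(self, p: OrientedPath) -> None:
        for v, _ in p.steps:
            self.lab(v)
        for a, b in zip(p.steps, p.steps[1:]):
            self.step_edge(a, b)

    def spell(self, p: OrientedPath) -> str:
        return spell_path(p, self)[0]

    def induced(self, keep: Iterable[str]) -> "BidirectedDNAGraph":
        """Subgraph induced on ``keep`` (edge set restricted, not re-closed)."""
        keep = frozenset(keep)
        edges = [
            e for e in self.edges if all(v in keep for v, _ in _edge_pairs(e))
        ]
        return BidirectedDNAGraph(keep, self.k, edges=edges)


def _edge_pairs(e: Edge) -> tuple[tuple[str, int], ...]:
    """The two (vertex, side) endpoints of an edge; a palindromic loop twice."""
    pairs = tuple(sorted(e))
    return pairs if len(pairs) == 2 else pairs * 2


def _edge_key(e: Edge):
    return tuple(sorted(e))


def is_loop(e: Edge) -> bool:
    return len({v for v, _ in e}) == 1


def build_dbg(K: CanonicalKmerSet) -> BidirectedDNAGraph:
    """Node-centric bidirected de Bruijn graph of K (one vertex per canonical k-mer)."""
    if not K.kmers:
        raise GraphError("cannot build a de Bruijn graph from an empty k-mer set")
    return BidirectedDNAGraph(K.kmers, K.k)


def spell_path(p: OrientedPath, g: BidirectedDNAGraph) -> tuple[str, list[int]]:
    """Glue the oriented occurrences of ``p`` left to right.

    Returns the spelled string and the start offset of every step's occurrence
    within it. Raises if consecutive steps are not connected in ``g``.
    """
    g.check_path(p)
    k = g.k
    v0, o0 = p.steps[0]
    out = [orient(v0, o0)]
    offsets = [0]
    pos = len(out[0])
    for (va, oa), (vb, ob) in zip(p.steps, p.steps[1:]):
        occ = orient(vb, ob)
        prev_occ = orient(va, oa)
        if prev_occ[-(k - 1) :] != occ[: k - 1]:
            raise GraphError(
                f"steps ({va},{oa}) -> ({vb},{ob}) do not overlap by k-1"
            )
        offsets.append(pos - (k - 1))
        out.append(occ[k - 1 :])
        pos += len(occ) - (k - 1)
    return "".join(out), offsets


# ---------------------------------------------------------------------------
# Unitigs and compaction


def _mergeable_edges(g: BidirectedDNAGraph) -> dict[tuple[str, int], Edge]:
    """Map (vertex, side) -> the unique mergeable edge there, if any.

    An edge is mergeable iff it is not a loop and it is the only edge on both
    of the sides it touches; loops never participate in unitigs.
    """
    merge: dict[tuple[str, int], Edge] = {}
    for e in g.edges:
        if is_loop(e):
            continue
        (u, su), (v, sv) = sorted(e)
        if len(g.incident(u, su)) == 1 and len(g.incident(v, sv)) == 1:
            merge[(u, su)] = e
            merge[(v, sv)] = e
    return merge


def _walk_chain(
    g: BidirectedDNAGraph,
    merge: Mapping[tuple[str, int], Edge],
    start: tuple[str, int],
) -> tuple[list[tuple[str, int]], bool]:
    """Follow mergeable edges forward from oriented ``start``.

    Returns the chain of oriented steps and whether it closed into a cycle.
    """
    steps = [start]
    seen = {start[0]}
    v, o = start
    while True:
        e = merge.get((v, 1 - o))  # exit side
        if e is None:
            return steps, False
        (a, sa), (b, sb) = _edge_pairs(e)
        if (a, sa) == (v, 1 - o):
            nxt, entry = b, sb
        else:
            nxt, entry = a, sa
        if nxt == steps[0][0] and entry == steps[0][1]:
            return steps, True  # closed cycle
        if nxt in seen:  # pragma: no cover - cannot happen with degree-1 sides
            raise GraphError("unitig walk revisited a vertex without closing")
        steps.append((nxt, entry))
        seen.add(nxt)
        v, o = nxt, entry


def _normalize_path(p: OrientedPath, g: BidirectedDNAGraph) -> OrientedPath:
    """Flip so the spelling is canonical; ties broken on the step tuples."""
    s = g.spell(p)
    rc = reverse_complement(s)
    if rc < s:
        return p.flipped()
    if rc == s:
        q = p.flipped()
        return min(p, q, key=lambda x: x.steps)
    return p


def maximal_unitigs(g: BidirectedDNAGraph) -> list[OrientedPath]:
    """Unique decomposition of the vertices into maximal non-branching paths.

    A connected component that is a perfect cycle of mergeable edges is broken
    at its lexicographically smallest vertex, which becomes the unitig start.
    Result is sorted by spelling (deterministic).
    """
    merge = _mergeable_edges(g)
    visited: set[str] = set()
    unitigs: list[OrientedPath] = []
    for v in sorted(g.vertices):
        if v in visited:
            continue
        # Walk backwards to find the chain start (or detect a cycle).
        back, is_cycle = _walk_chain(g, merge, (v, 1))  # arbitrary orientation
        if is_cycle:
            cyc_vertices = [u for u, _ in back]
            vmin = min(cyc_vertices)
            # Two directions leave vmin; pick the lexicographically smaller spelling.
            cands = []
            for o in (0, 1):
                steps, closed = _walk_chain(g, merge, (vmin, o))
                assert closed and len(steps) == len(cyc_vertices)
                cands.append(OrientedPath(tuple(steps)))
            p = min(cands, key=lambda q: (g.spell(q), q.steps))
        else:
            # back ends at a chain endpoint; restart there in reverse direction.
            end_v, end_o = back[-1]
            steps, closed = _walk_chain(g, merge, (end_v, 1 - end_o))
            assert not closed
            p = _normalize_path(OrientedPath(tuple(steps)), g)
        unitigs.append(p)
        visited.update(p.vertices)
    unitigs.sort(key=lambda q: g.spell(q))
    return unitigs


def compact(g: BidirectedDNAGraph) -> BidirectedDNAGraph:
    """Compacted graph: vertices are maximal unitigs labeled by canonical spellings."""
    labels = [canonicalize(g.spell(p)) for p in maximal_unitigs(g)]
    if len(set(labels)) != len(labels):  # pragma: no cover - spellings are distinct
        raise GraphError("duplicate unitig spellings")
    return BidirectedDNAGraph(labels, g.k)


# ---------------------------------------------------------------------------
# GFA export (debugging aid; not consumed anywhere)


def to_gfa1(g: BidirectedDNAGraph) -> str:
    """GFA1 dump: segments are labels, links carry +/- orientations and (k-1)M."""
    lines = ["H\tVN:Z:1.0"]
    names = {v: f"s{i+1}" for i, v in enumerate(sorted(g.vertices))}
    for v in sorted(g.vertices):
        lines.append(f"S\t{names[v]}\t{v}")
    ov = f"{g.k - 1}M"
    for e in sorted(g.edges, key=_edge_key):
        (u, su), (v, sv) = _edge_pairs(e)
        # From u exiting side su (occurrence orientation 1-su) into v side sv.
        fo = "+" if su == 1 else "-"
        to = "+" if sv == 0 else "-"
        lines.append(f"L\t{names[u]}\t{fo}\t{names[v]}\t{to}\t{ov}")
    return "\n".join(lines) + "\n"
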