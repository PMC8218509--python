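"""Dead-end-centric compression: a shallow, marker-free variant.

Dead-end vertices (tips) of the compacted graph - typically artifacts of
sequencing errors or coverage gaps - are each placed in their own singleton
cover path; the rest of the graph is covered greedily. Each tip is then
absorbed directly into a neighboring non-tip path, so the absorption forest
has depth at most two, brackets never nest, and the decoder needs no stack.

Because the bracket groups carry no marker character, the absorbed overhang
must be reattachable by the decoder's only rule: prepend the k-1 outer
characters left of "[". That works exactly when the absorption edge attaches
at the *back* side of the parent occurrence (an implicit "+"); a tip whose
only attachments are front-side cannot be encoded marker-free and is left as
its own root (the same fallback the skip rule uses for tips with no non-tip
neighbor). Each successful absorption trades k-1 nucleotides for 2 brackets.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from .absorption import AbsorptionEdge, OutForest
from .bidigraph import (
    BidirectedDNAGraph,
    OrientedPath,
    _edge_pairs,
    build_dbg,
    compact,
    is_loop,
)
from .encoder import ENRICHED_ALPHABET, CompressionResult, encode_cover
from .errors import FormatError
from .kmerset import CanonicalKmerSet
from .pathcover import PathCover, greedy_path_cover


def tip_path_cover(cdbg: BidirectedDNAGraph) -> PathCover:
    """Greedy cover of the non-dead-end subgraph plus one singleton per dead-end."""
    dead = sorted(v for v in cdbg.vertices if cdbg.is_dead_end(v))
    keep = cdbg.vertices - set(dead)
    paths: list[OrientedPath] = []
    if keep:
        sub = cdbg.induced(keep)
        paths.extend(greedy_path_cover(sub).paths)
    paths.extend(OrientedPath(((v, 0),)) for v in dead)
    return PathCover(paths, cdbg)


def tip_forest(cdbg: BidirectedDNAGraph, cover: PathCover) -> OutForest:
    """Depth-<=2 forest: each encodable dead-end hangs off one non-tip neighbor.

    For each dead-end v, candidate attachments are edges to non-dead-end
    vertices that hit the *back* side of the neighbor's occurrence in its
    cover path (marker-free encodable); the lexicographically smallest
    candidate wins. Tips with no candidate stay roots.
    """
    parent_of: dict[int, tuple[int, AbsorptionEdge]] = {}
    for v in sorted(cdbg.vertices):
        if not cdbg.is_dead_end(v):
            continue
        (used_side,) = {0, 1} - cdbg.dead_end_sides(v)
        candidates = []
        for e in cdbg.incident(v, used_side):
            if is_loop(e):
                continue
            for (a, sa), (b, sb) in (_edge_pairs(e), _edge_pairs(e)[::-1]):
                if (a, sa) != (v, used_side):
                    continue
                u, su = b, sb
                if cdbg.is_dead_end(u):
                    continue
                pid, pos = cover.position_of(u)
                o_u = cover.paths[pid].steps[pos][1]
                if su != 1 - o_u:  # front-side attachment: not marker-free encodable
                    continue
                candidates.append((u, su, sa, e, pid))
        if not candidates:
            continue
        u, su, sv, e, pid = min(candidates)
        parent_of[cover.path_of(v)] = (
            pid,
            AbsorptionEdge(
                parent_path=pid,
                child_path=cover.path_of(v),
                parent_vertex=u,
                child_vertex=v,
                parent_side=su,
                child_side=sv,
                cdbg_edge=e,
            ),
        )
    roots = tuple(sorted(set(range(len(cover))) - set(parent_of)))
    return OutForest(parent_of=parent_of, roots=roots)


def ess_tip_compress(K: CanonicalKmerSet) -> CompressionResult:
    """Full tip-mode pipeline; weight = |K| + |Psi|(k-1) - (k-3) * #absorbed."""
    cdbg = compact(build_dbg(K))
    cover = tip_path_cover(cdbg)
    forest = tip_forest(cdbg, cover)
    return encode_cover(cdbg, cover, forest, mode="tip")


def dec_tip(x: str, k: int) -> list[str]:
    """Tip-mode decoder: bracket content c decodes to (k-1 outer chars left) + c.

    Brackets must not nest and no marker characters may appear.
    """
    if not set(x) <= ENRICHED_ALPHABET:
        raise FormatError(f"invalid characters in enriched string {x[:40]!r}")
    if "+" in x or "-" in x:
        raise FormatError("marker characters are not allowed in tip mode")
    outer_parts: list[str] = []
    out_children: list[str] = []
    depth = 0
    group_start = 0
    for i, ch in enumerate(x):
        if ch == "[":
            if depth == 1:
                raise FormatError("nested brackets are not allowed in tip mode")
            depth = 1
            outer = "".join(outer_parts)
            if len(outer) < k - 1:
                raise FormatError(
                    f"fewer than k-1 outer characters before '[' at index {i}"
                )
            out_children.append(outer[-(k - 1) :])  # prefix; content appended at ']'
            group_start = i + 1
        elif ch == "]":
            if depth == 0:
                raise FormatError(f"unbalanced ']' at index {i}")
            depth = 0
            out_children[-1] += x[group_start:i]
        elif depth == 0:
            outer_parts.append(ch)
    if depth != 0:
        raise FormatError("unbalanced '[' in enriched string")
    emitted = "".join(outer_parts)
    if len(emitted) < k:
        raise FormatError(f"decoded string {emitted!r} is shorter than k={k}")
    for s in out_children:
        if len(s) < k:
            raise FormatError(f"decoded tip {s!r} is shorter than k={k}")
    return [emitted] + out_children
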