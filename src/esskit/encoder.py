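"""Enriched-string encoder: splice absorbed cover paths into their parents.

The driver builds dBG(K) -> cdBG(K) -> greedy cover -> absorption digraph ->
edge-maximizing out-forest, then emits one enriched string per forest root.

Spelling geometry. Each absorbed child attaches at a specific side s_p of its
parent vertex's occurrence inside the parent spelling. If s_p is the *back*
side of the occurrence (s_p == 1 - orientation), the shared (k-1)-mer is the
window ending at the occurrence's last character and the child's spelling
prefix equals that window, so its prefix is replaced by "+". If s_p is the
*front* side, the window starts at the occurrence's first character and equals
the reverse complement of the child's prefix, giving "-". In both cases the
bracket group "[" + marker + rest-of-child + "]" is spliced immediately after
the window, so the decoder's rule (marker := the rightmost k-1 outer
characters left of the open bracket) inverts the construction exactly.

Children are always flipped so the absorbed endpoint is their initiator and
the removed (k-1)-mer is their spelling prefix; each absorption trades k-1
nucleotides for 3 extra characters (two brackets, one marker), so the final
weight is |K| + 3*|Psi| + n_sc*(k-4) with n_sc output strings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .absorption import (
    AbsorptionEdge,
    OutForest,
    build_absorption_digraph,
    condensation,
    find_absorption_edges,
    max_edge_spanning_out_forest,
)
from .bidigraph import BidirectedDNAGraph, OrientedPath, build_dbg, compact, orient, spell_path
from .errors import FormatError, GraphError
from .kmerset import CanonicalKmerSet, reverse_complement
from .pathcover import (
    CoverBound,
    PathCover,
    cover_lower_bound,
    ess_weight_lower_bound,
    greedy_path_cover,
    weight,
)

ENRICHED_ALPHABET = set("ACGT[]+-")


@dataclass(frozen=True)
class CompressionResult:
    """The enriched string set plus all bookkeeping the weight theory predicts."""

    strings: tuple[str, ...]
    mode: str  # "ess" | "tip"
    k: int
    num_kmers: int
    num_paths: int
    n_sc: int
    weight: int
    predicted_weight: int
    lower_bound: int
    spss_weight: int  # |K| + |Psi|(k-1) for the same cover
    num_absorbed: int
    bound: CoverBound
    per_path_chars: dict[int, int]  # n_psi accounting per cover path

    @property
    def chars_per_kmer(self) -> float:
        return self.weight / self.num_kmers

    def stats(self) -> dict:
        return {
            "mode": self.mode,
            "k": self.k,
            "num_kmers": self.num_kmers,
            "num_strings": len(self.strings),
            "num_paths": self.num_paths,
            "n_sc": self.n_sc,
            "num_absorbed": self.num_absorbed,
            "weight": self.weight,
            "predicted_weight": self.predicted_weight,
            "spss_weight": self.spss_weight,
            "lower_bound": self.lower_bound,
            "beta": self.bound.beta,
            "C": self.bound.C,
            "chars_per_kmer": round(self.chars_per_kmer, 4),
        }


def predicted_weight(num_kmers: int, num_paths: int, n_sc: int, k: int) -> int:
    """|K| + 3*|Psi| + n_sc*(k-4); reduces to the cover weight when n_sc == |Psi|."""
    if n_sc > num_paths:
        raise ValueError("n_sc cannot exceed the number of paths")
    return num_kmers + 3 * num_paths + n_sc * (k - 4)


# ---------------------------------------------------------------------------
# Core recursion (shared by ess and tip modes)


def _arrange_child(cover: PathCover, ae: AbsorptionEdge) -> OrientedPath:
    """Flip/orient the child path so the absorbed vertex initiates with side s_c."""
    p = cover.paths[ae.child_path]
    cv, cs = ae.child_vertex, ae.child_side
    if len(p) == 1:
        return OrientedPath(((cv, cs),))
    if p.steps[0][0] == cv:
        cand = p
    elif p.steps[-1][0] == cv:
        cand = p.flipped()
    else:
        raise GraphError(f"child vertex {cv!r} is not an endpoint of its path")
    if cand.steps[0] != (cv, cs):
        raise GraphError(
            f"absorption edge attaches at the inner side of child endpoint {cv!r}"
        )
    return cand


def _splice_point(
    spell: str,
    offsets: list[int],
    arranged: OrientedPath,
    ae: AbsorptionEdge,
    k: int,
) -> tuple[int, str]:
    """Insertion index in parent-spelling coordinates and the shared window."""
    i = arranged.vertices.index(ae.parent_vertex)
    o = arranged.steps[i][1]
    off = offsets[i]
    L = len(ae.parent_vertex)
    if ae.parent_side == 1 - o:  # back of the occurrence
        ins = off + L
    elif ae.parent_side == o:  # front of the occurrence
        ins = off + (k - 1)
    else:  # pragma: no cover
        raise GraphError("invalid parent side")
    window = spell[ins - (k - 1) : ins]
    if ins < k - 1:  # pragma: no cover - geometry guarantees ins >= k-1
        raise GraphError("insertion point lacks k-1 preceding characters")
    return ins, window


def spell_path_enrich(
    cdbg: BidirectedDNAGraph,
    cover: PathCover,
    forest: OutForest,
    *,
    tip: bool = False,
) -> tuple[list[str], dict[int, int]]:
    """Emit one enriched string per forest root; also per-path character counts.

    Implements the recursive spell-and-splice bottom-up (children before
    parents) so deep absorption chains do not hit the interpreter stack limit.
    """
    k = cdbg.k
    arrangement: dict[int, OrientedPath] = {}
    marker_of: dict[int, str] = {}
    splices: dict[int, list[tuple[int, int]]] = {pid: [] for pid in range(len(cover))}
    order: list[int] = []

    for r in forest.roots:
        arrangement[r] = cover.paths[r]
    spell_cache: dict[int, tuple[str, list[int]]] = {}
    stack = sorted(forest.roots, reverse=True)
    while stack:
        pid = stack.pop()
        order.append(pid)
        sp, offsets = spell_path(arrangement[pid], cdbg)
        spell_cache[pid] = (sp, offsets)
        for child, ae in forest.children_of(pid):
            arranged_child = _arrange_child(cover, ae)
            ins, window = _splice_point(sp, offsets, arrangement[pid], ae, k)
            child_spell_prefix = orient(ae.child_vertex, ae.child_side)[: k - 1]
            if child_spell_prefix == window:
                marker = "+"
            elif child_spell_prefix == reverse_complement(window):
                marker = "-"
            else:
                raise GraphError(
                    f"absorption edge {ae} shares no (k-1)-mer with its window"
                )
            if tip and marker != "+":
                raise GraphError(
                    "tip-mode absorption must attach at the back of the parent "
                    "occurrence (implicit '+' marker)"
                )
            arrangement[child] = arranged_child
            marker_of[child] = marker
            splices[pid].append((ins, child))
            stack.append(child)

    # Bottom-up assembly: children appear later in `order` than their parents.
    enriched: dict[int, str] = {}
    per_path: dict[int, int] = {}
    for pid in reversed(order):
        sp, _ = spell_cache[pid]
        parts: list[str] = []
        pos = 0
        for ins, child in sorted(splices[pid]):
            parts.append(sp[pos:ins])
            parts.append("[" + enriched[child] + "]")
            pos = ins
        parts.append(sp[pos:])
        body = "".join(parts)
        if pid in marker_of:  # absorbed: drop the redundant (k-1)-mer prefix
            if tip:
                enriched[pid] = body[k - 1 :]
                per_path[pid] = len(sp) - (k - 3)
            else:
                enriched[pid] = marker_of[pid] + body[k - 1 :]
                per_path[pid] = len(sp) - (k - 4)
        else:
            enriched[pid] = body
            per_path[pid] = len(sp)
    roots_sorted = sorted(forest.roots)
    return [enriched[r] for r in roots_sorted], per_path


# ---------------------------------------------------------------------------
# Driver


def encode_cover(
    cdbg: BidirectedDNAGraph,
    cover: PathCover,
    forest: OutForest | None = None,
    *,
    mode: str = "ess",
) -> CompressionResult:
    """Run the absorption machinery on an explicit cover (fixture injection point)."""
    k = cdbg.k
    if forest is None:
        edges = find_absorption_edges(cdbg, cover)
        da = build_absorption_digraph(edges, cover)
        forest = max_edge_spanning_out_forest(da)
        n_sc = len(forest.roots)
        _, n_sc_check = condensation(da)
        assert n_sc == n_sc_check
    else:
        n_sc = len(forest.roots)
    strings, per_path = spell_path_enrich(cdbg, cover, forest, tip=(mode == "tip"))
    w = weight(strings)
    if sum(per_path.values()) != w:  # pragma: no cover
        raise GraphError("per-path character accounting does not sum to the weight")
    num_kmers = cdbg.num_kmers()
    num_paths = len(cover)
    num_absorbed = forest.n_arcs
    spss_w = num_kmers + num_paths * (k - 1)
    bound = cover_lower_bound(cdbg)
    lb = ess_weight_lower_bound(num_kmers, bound, k)
    if mode == "ess":
        pred = predicted_weight(num_kmers, num_paths, n_sc, k)
    else:
        pred = spss_w - (k - 3) * num_absorbed
    if w != pred:
        raise GraphError(
            f"weight {w} does not match the predicted weight {pred} "
            f"(|K|={num_kmers}, |Psi|={num_paths}, n_sc={n_sc}, k={k}) - encoder bug"
        )
    if k > 4 and w < lb:
        raise GraphError(f"weight {w} below the lower bound {lb} - bookkeeping bug")
    if mode == "ess":
        n_markers = sum(s.count("+") + s.count("-") for s in strings)
        if n_markers != num_paths - n_sc:
            raise GraphError(
                f"marker count {n_markers} != |Psi| - n_sc = {num_paths - n_sc}"
            )
    return CompressionResult(
        strings=tuple(strings),
        mode=mode,
        k=k,
        num_kmers=num_kmers,
        num_paths=num_paths,
        n_sc=n_sc,
        weight=w,
        predicted_weight=pred,
        lower_bound=lb,
        spss_weight=spss_w,
        num_absorbed=num_absorbed,
        bound=bound,
        per_path_chars=per_path,
    )


def ess_compress(K: CanonicalKmerSet) -> CompressionResult:
    """Full pipeline: dBG -> cdBG -> greedy cover -> absorption forest -> strings."""
    cdbg = compact(build_dbg(K))
    cover = greedy_path_cover(cdbg)
    return encode_cover(cdbg, cover, mode="ess")


# ---------------------------------------------------------------------------
# ESS file format

_HEADER_PREFIX = "#ESS"


def write_ess(result: CompressionResult, path: str | Path) -> None:
    """Bit-exact format: header line, then one enriched string per line (LF)."""
    from .kmerset import open_text

    with open_text(path, "wt") as fh:
        fh.write(
            f"#ESS\tv1\tk={result.k}\tmode={result.mode}\tn={len(result.strings)}\n"
        )
        for s in result.strings:
            fh.write(s + "\n")


def read_ess(path: str | Path) -> tuple[int, str, list[str]]:
    """Parse an ESS file; returns (k, mode, strings)."""
    from .kmerset import open_text

    with open_text(path) as fh:
        header = fh.readline().rstrip("\n")
        fields = header.split("\t")
        if len(fields) != 5 or fields[0] != _HEADER_PREFIX or fields[1] != "v1":
            raise FormatError(f"{path}: bad ESS header {header!r}")
        try:
            k = int(fields[2].removeprefix("k="))
            mode = fields[3].removeprefix("mode=")
            n = int(fields[4].removeprefix("n="))
        except ValueError as exc:
            raise FormatError(f"{path}: bad ESS header {header!r}") from exc
        if mode not in ("ess", "tip"):
            raise FormatError(f"{path}: unknown mode {mode!r}")
        strings = [line.rstrip("\n") for line in fh if line.strip()]
    if len(strings) != n:
        raise FormatError(f"{path}: header promises {n} strings, found {len(strings)}")
    for s in strings:
        if not set(s) <= ENRICHED_ALPHABET:
            raise FormatError(f"{path}: invalid characters in record {s[:40]!r}")
    return k, mode, strings
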