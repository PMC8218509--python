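"""Recursive decompressor: enriched strings -> SPSS -> canonical k-mer set.

The decoder is a pure string algorithm: it never sees the graph, so it can be
tested on hand-written enriched strings independently of the encoder. For each
string it (1) replaces every outer "+" by the current marker replacement and
every outer "-" by its reverse complement, (2) emits the outer characters as
one string, and (3) recurses into each top-level bracket group, passing as the
new marker replacement the rightmost k-1 outer characters (post-substitution)
to the left of the open bracket. Substitution happens before the replacement
windows are read, which is what makes bracket groups adjacent to a substituted
prefix decode correctly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from .encoder import ENRICHED_ALPHABET, read_ess
from .errors import FormatError, SpssViolationError
from .kmerset import CanonicalKmerSet, canonicalize, reverse_complement
from .pathcover import SPSS


def dec(x: str, marker_replacement: str | None, k: int) -> list[str]:
    """Decode one enriched string; returns the emitted strings in stable order.

    The outer string comes first, then each bracket group's strings depth-first
    in order of appearance. ``marker_replacement`` is None only for roots.
    Iterative (an explicit stack), so nesting depth is unbounded.
    """
    out: list[str] = []
    stack: list[tuple[str, str | None]] = [(x, marker_replacement)]
    while stack:
        content, mr = stack.pop()
        emitted, children = _dec_one(content, mr, k)
        out.append(emitted)
        stack.extend(reversed(children))
    return out


def _dec_one(
    x: str, marker_replacement: str | None, k: int
) -> tuple[str, list[tuple[str, str]]]:
    """One recursion level: the outer string and (content, replacement) children."""
    if not set(x) <= ENRICHED_ALPHABET:
        raise FormatError(f"invalid characters in enriched string {x[:40]!r}")
    outer_parts: list[str] = []
    children: list[tuple[str, str]] = []  # (content, marker replacement)
    depth = 0
    group_start = 0
    for i, ch in enumerate(x):
        if ch == "[":
            depth += 1
            if depth == 1:
                outer = "".join(outer_parts)
                if len(outer) < k - 1:
                    raise FormatError(
                        f"fewer than k-1 outer characters before '[' at index {i}"
                    )
                children.append((None, outer[-(k - 1) :]))  # content filled at ']'
                group_start = i + 1
        elif ch == "]":
            depth -= 1
            if depth < 0:
                raise FormatError(f"unbalanced ']' at index {i}")
            if depth == 0:
                children[-1] = (x[group_start:i], children[-1][1])
        elif depth == 0:
            if ch == "+":
                if marker_replacement is None:
                    raise FormatError("outer '+' in a root enriched string")
                outer_parts.append(marker_replacement)
            elif ch == "-":
                if marker_replacement is None:
                    raise FormatError("outer '-' in a root enriched string")
                outer_parts.append(reverse_complement(marker_replacement))
            else:
                outer_parts.append(ch)
    if depth != 0:
        raise FormatError("unbalanced '[' in enriched string")
    emitted = "".join(outer_parts)
    if len(emitted) < k:
        raise FormatError(f"decoded string {emitted!r} is shorter than k={k}")
    return emitted, children


def decompress(ess_file: str | Path) -> SPSS:
    """Decode every record of an ESS file into an SPSS (stable record order)."""
    from .tipmode import dec_tip

    k, mode, records = read_ess(ess_file)
    strings: list[str] = []
    for x in records:
        if mode == "ess":
            strings.extend(dec(x, None, k))
        else:
            strings.extend(dec_tip(x, k))
    return SPSS(strings=tuple(strings), k=k)


def decode_result(result) -> SPSS:
    """Decode an in-memory CompressionResult without touching the filesystem."""
    from .tipmode import dec_tip

    strings: list[str] = []
    for x in result.strings:
        if result.mode == "ess":
            strings.extend(dec(x, None, result.k))
        else:
            strings.extend(dec_tip(x, result.k))
    return SPSS(strings=tuple(strings), k=result.k)


def kmers_in_spss_order(s: SPSS, k: int | None = None) -> list[str]:
    """Canonical k-mers enumerated string-by-string, left to right.

    This is the deterministic ordering used to co-compress per-k-mer values
    (e.g. abundance counts) in a separate file. Raises on any duplicate.
    """
    k = s.k if k is None else k
    seen: set[str] = set()
    out: list[str] = []
    for string in s.strings:
        if len(string) < k:
            raise SpssViolationError(f"SPSS string {string!r} shorter than k={k}")
        for i in range(len(string) - k + 1):
            x = canonicalize(string[i : i + k])
            if x in seen:
                raise SpssViolationError(f"duplicate k-mer {x!r} in SPSS")
            seen.add(x)
            out.append(x)
    return out


def spss_to_kmers(s: SPSS, k: int | None = None) -> CanonicalKmerSet:
    """Canonical k-mer set of an SPSS; raises on duplicates (SPSS violation)."""
    k = s.k if k is None else k
    return CanonicalKmerSet(k=k, kmers=frozenset(kmers_in_spss_order(s, k)))


def write_spss_fasta(s: SPSS, path: str | Path) -> None:
    """SPSS as FASTA, records named path_0001, path_0002, ..."""
    from .kmerset import open_text

    with open_text(path, "wt") as fh:
        for i, string in enumerate(s.strings, 1):
            fh.write(f">path_{i:04d}\n{string}\n")
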