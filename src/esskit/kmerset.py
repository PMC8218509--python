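"""Canonical k-mer sets: extraction, counting, abundance filtering, file I/O.

A k-mer is *canonical* if it is the lexicographically smaller of itself and its
reverse complement. All downstream graph machinery works on canonical k-mers,
which is well defined only for odd k (no odd-length DNA string equals its own
reverse complement), so even k is rejected throughout.
"""

from __future__ import annotations

import gzip
import lzma
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import AlphabetError, FormatError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ACGT_RUN = re.compile(r"[ACGT]+")
_VALID = re.compile(r"[ACGT]+\Z")


def _check_dna(x: str) -> str:
    if not x or not _VALID.match(x):
        raise AlphabetError(f"not a nonempty string over ACGT: {x!r}")
    return x


def reverse_complement(x: str) -> str:
    """Reverse complement of an uppercase ACGT string.

    Applying it twice is the identity.
    """
    _check_dna(x)
    return x.translate(_COMPLEMENT)[::-1]


def canonicalize(x: str) -> str:
    """Lexicographically smaller of ``x`` and its reverse complement (idempotent)."""
    _check_dna(x)
    rc = x.translate(_COMPLEMENT)[::-1]
    return x if x <= rc else rc


def _check_k(k: int) -> int:
    if k % 2 == 0:
        raise ValueError(
            f"k must be odd (even k admits k-mers equal to their own reverse "
            f"complement, making the canonical set ill-defined), got {k}"
        )
    if k < 3:
        raise ValueError(f"k must be >= 3, got {k}")
    return k


@dataclass(frozen=True)
class CanonicalKmerSet:
    """A finite set of canonical k-mers together with k (odd, >= 3)."""

    k: int
    kmers: frozenset[str]

    def __post_init__(self) -> None:
        _check_k(self.k)
        for x in self.kmers:
            if len(x) != self.k:
                raise ValueError(f"k-mer {x!r} does not have length {self.k}")
            if canonicalize(x) != x:
                raise ValueError(f"k-mer {x!r} is not canonical")

    @classmethod
    def from_kmers(cls, kmers: Iterable[str], k: int | None = None) -> "CanonicalKmerSet":
        """Canonicalize and deduplicate ``kmers``; infer k from them if not given."""
        canon = frozenset(canonicalize(x) for x in kmers)
        if k is None:
            lengths = {len(x) for x in canon}
            if len(lengths) != 1:
                raise FormatError(f"k-mers have ragged lengths: {sorted(lengths)}")
            k = lengths.pop()
        return cls(k=k, kmers=canon)

    def __len__(self) -> int:
        return len(self.kmers)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.kmers))

    def __contains__(self, x: str) -> bool:
        return canonicalize(x) in self.kmers


def count_kmers(sequences: Iterable[str], k: int) -> Counter[str]:
    """Exact in-memory canonical k-mer counts over all clean length-k windows.

    Windows containing any non-ACGT symbol are skipped: each sequence is split
    into maximal ACGT-only runs (the usual k-mer-counter convention for N).
    """
    _check_k(k)
    counts: Counter[str] = Counter()
    for seq in sequences:
        for run in _ACGT_RUN.findall(seq.upper()):
            for i in range(len(run) - k + 1):
                counts[canonicalize(run[i : i + k])] += 1
    return counts


def extract_kmers(
    sequences: Iterable[str], k: int, min_count: int = 1
) -> CanonicalKmerSet:
    """Canonical k-mers occurring at least ``min_count`` times across ``sequences``."""
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    counts = count_kmers(sequences, k)
    return CanonicalKmerSet(
        k=k, kmers=frozenset(x for x, c in counts.items() if c >= min_count)
    )


# ---------------------------------------------------------------------------
# File I/O


def open_text(path: str | Path, mode: str = "rt"):
    """Open plain, gzip or xz text transparently (by magic bytes when reading)."""
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(6)
        if magic[:2] == b"\x1f\x8b":
            return gzip.open(path, mode)
        if magic == b"\xfd7zXZ\x00":
            return lzma.open(path, mode)
        return open(path, mode)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    if path.suffix == ".xz":
        return lzma.open(path, mode)
    return open(path, mode)


def read_sequences(path: str | Path) -> list[str]:
    """Read sequences from FASTA or FASTQ (plain or gzip/xz), sniffing the format."""
    from Bio import SeqIO

    with open_text(path) as fh:
        head = fh.read(1)
        fh.seek(0)
        if head == ">":
            fmt = "fasta"
        elif head == "@":
            fmt = "fastq"
        else:
            raise FormatError(f"{path}: not FASTA or FASTQ (starts with {head!r})")
        return [str(rec.seq) for rec in SeqIO.parse(fh, fmt)]


def write_kmer_file(kmers: CanonicalKmerSet, path: str | Path) -> None:
    """One canonical k-mer per line, uppercase, sorted, LF endings (diffable)."""
    with open_text(path, "wt") as fh:
        for x in sorted(kmers.kmers):
            fh.write(x + "\n")


def read_kmer_file(path: str | Path) -> CanonicalKmerSet:
    """Read a one-k-mer-per-line file; canonicalizes, deduplicates, infers k."""
    kmers: list[str] = []
    k = None
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            x = line.strip().upper()
            if not x:
                continue
            if k is None:
                k = len(x)
            elif len(x) != k:
                raise FormatError(
                    f"{path}:{lineno}: line length {len(x)} != first line length {k}"
                )
            kmers.append(canonicalize(_check_dna(x)))
    if k is None:
        raise FormatError(f"{path}: empty k-mer file")
    _check_k(k)
    return CanonicalKmerSet(k=k, kmers=frozenset(kmers))
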