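"""Synthetic genomes, error-bearing reads, and hand-built graph fixtures.

The read simulator emulates shotgun sequencing at a chosen coverage with
i.i.d. substitution errors (no indels): substitutions are what create the
tips and bubbles the absorption machinery exploits, so this is sufficient to
produce de Bruijn graphs with many dead-ends, branches, and multiple
components without any external downloads. All randomness flows through an
explicit seed; equal configurations give byte-identical outputs.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .absorption import AbsorptionEdge, OutForest
from .bidigraph import BidirectedDNAGraph, OrientedPath, build_dbg
from .kmerset import CanonicalKmerSet, reverse_complement
from .pathcover import PathCover

_BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Shotgun-read simulation parameters."""

    genome_length: int = 100_000
    read_length: int = 100
    coverage: float = 10.0
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length > self.genome_length:
            raise ValueError("read_length must not exceed genome_length")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


def random_genome(length: int, seed: int) -> str:
    """Uniform i.i.d. ACGT string of the given length; reproducible per seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = random.Random(seed)
    return "".join(rng.choices(_BASES, k=length))


def simulate_reads(genome: str, cfg: SimConfig) -> list[str]:
    """ceil(coverage * |genome| / read_length) reads with substitution errors.

    Start positions are uniform, each strand is used with probability 1/2, and
    each base is substituted independently at ``error_rate``.
    """
    rng = random.Random(cfg.seed)
    n_reads = math.ceil(cfg.coverage * len(genome) / cfg.read_length)
    reads: list[str] = []
    for _ in range(n_reads):
        start = rng.randrange(len(genome) - cfg.read_length + 1)
        read = genome[start : start + cfg.read_length]
        if rng.random() < 0.5:
            read = reverse_complement(read)
        if cfg.error_rate > 0:
            chars = list(read)
            for i in range(len(chars)):
                if rng.random() < cfg.error_rate:
                    chars[i] = rng.choice(_BASES.replace(chars[i], ""))
            read = "".join(chars)
        reads.append(read)
    return reads


def write_fasta(sequences: Iterable[str], path: str | Path) -> None:
    from .kmerset import open_text

    with open_text(path, "wt") as fh:
        for i, seq in enumerate(sequences, 1):
            fh.write(f">seq_{i}\n{seq}\n")


# ---------------------------------------------------------------------------
# Graph fixtures
#
# Each fixture bundles a graph built from an explicit k-mer list with, where
# useful, a hand-injected cover and absorption forest, so encoder tests do not
# depend on the greedy cover heuristics.


@dataclass
class FixtureGraph:
    name: str
    graph: BidirectedDNAGraph
    cover: PathCover | None = None
    forest: OutForest | None = None


def _dbg_fixture(kmers: list[str], k: int) -> BidirectedDNAGraph:
    return build_dbg(CanonicalKmerSet.from_kmers(kmers, k))


def toy_absorb() -> FixtureGraph:
    """Two-path cover of the 5 canonical 3-mers of {TCGTT, GTAA}.

    The parent path spells TCGT with internal vertex ACG (occurrence CGT);
    the child path spells GTAA and is absorbed at the shared GT, encoding to
    TCGT[+AA]T. The graph here is the uncompacted de Bruijn graph with the
    figure-style cover injected (the greedy cover of the *compacted* graph
    merges this K into a single path instead).
    """
    g = _dbg_fixture(["TCG", "CGT", "GTT", "GTA", "TAA"], 3)
    parent = OrientedPath((("CGA", 1), ("ACG", 1), ("AAC", 1)))  # spells TCGT
    child = OrientedPath((("GTA", 0), ("TAA", 0)))  # spells GTAA
    cover = PathCover([parent, child], g)
    return FixtureGraph("toy_absorb", g, cover=cover)


def recursive3() -> FixtureGraph:
    """Three-level absorption chain: AAACC absorbs CCG which absorbs CGT.

    Encodes to AAACC[+G[+T]] under the injected forest (nesting depth 2).
    """
    g = _dbg_fixture(["AAA", "AAC", "ACC", "CCG", "CGT"], 3)
    p1 = OrientedPath((("AAA", 0), ("AAC", 0), ("ACC", 0)))  # AAACC
    p2 = OrientedPath((("CCG", 0),))
    p3 = OrientedPath((("ACG", 1),))  # occurrence CGT
    cover = PathCover([p1, p2, p3], g)
    pid = {cover.graph.spell(p): i for i, p in enumerate(cover.paths)}
    id1, id2, id3 = pid["AAACC"], pid["CCG"], pid["CGT"]
    e12 = frozenset({("ACC", 1), ("CCG", 0)})
    e23 = frozenset({("CCG", 1), ("ACG", 1)})
    forest = OutForest(
        parent_of={
            id2: (id1, AbsorptionEdge(id1, id2, "ACC", "CCG", 1, 0, e12)),
            id3: (id2, AbsorptionEdge(id2, id3, "CCG", "ACG", 1, 1, e23)),
        },
        roots=(id1,),
    )
    return FixtureGraph("recursive3", g, cover=cover, forest=forest)


def tip_chain() -> FixtureGraph:
    """A 3-unitig cdBG chain whose two end unitigs are dead-end tips (k=5).

    A chain of unitigs survives compaction only if the junctions are blocked;
    here both junction 4-mers (AATT and ACGT) are reverse-complement
    palindromes, whose self-overlap loops stop unitig extension. Compacting
    gives middle AATTACGT (no free side) and tips AATTCGG, ACGTCCA.
    """
    from .bidigraph import compact

    strings = ["CCGAATT", "AATTACGT", "ACGTCCA"]
    kmers = {s[i : i + 5] for s in strings for i in range(len(s) - 4)}
    return FixtureGraph("tip_chain", compact(_dbg_fixture(sorted(kmers), 5)))


def star() -> FixtureGraph:
    """A center 3-mer with one leaf on side 0 and two on side 1.

    Center AAC: side 0 reaches GAA (occurrence TTC), side 1 reaches ACA and
    ACT. Four dead-end sides in one component, so beta = 2, which brute force
    confirms is the true minimum cover size.
    """
    return FixtureGraph("star", _dbg_fixture(["TTC", "ACA", "ACT", "AAC"], 3))


def isolated() -> FixtureGraph:
    """Three isolated vertices (no overlaps at k=5)."""
    return FixtureGraph(
        "isolated", _dbg_fixture(["AAAAA", "CCCCC", "AGAGA"], 5)
    )


def cycle_component() -> FixtureGraph:
    """A component whose de Bruijn graph is a perfect cycle (circular 5-mers).

    The circular sequence was chosen (seeded search) so all 12 canonical
    5-mers are distinct and every vertex side carries exactly one edge.
    """
    cyc = "TGGGAAATCGCC"
    seq = cyc + cyc[:4]
    kmers = [seq[i : i + 5] for i in range(len(cyc))]
    return FixtureGraph("cycle_component", _dbg_fixture(kmers, 5))


def mutual_cycle() -> FixtureGraph:
    """A k-mer set whose greedy-cover absorption digraph contains a 2-cycle.

    The 5-mers of two short sequences, found by seeded search and frozen here
    so the SCC and starter-set logic is exercised by a real graph, not only by
    synthetic digraphs (tests assert the 2-cycle rather than assume it). Two
    of the three cover paths absorb each other mutually; the forest breaks the
    tie and the whole set compresses to a single enriched string that uses
    both marker characters.
    """
    sequences = ["ACCCTTTACAGGCCCTTC", "GGAATGGTCAGG"]
    kmers = {s[i : i + 5] for s in sequences for i in range(len(s) - 4)}
    return FixtureGraph("mutual_cycle", _dbg_fixture(sorted(kmers), 5))


def fixture_graphs() -> dict[str, FixtureGraph]:
    """All named fixtures keyed by name."""
    out = [
        toy_absorb(),
        recursive3(),
        tip_chain(),
        star(),
        isolated(),
        cycle_component(),
        mutual_cycle(),
    ]
    return {f.name: f for f in out}
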