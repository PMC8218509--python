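"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools
import random

import pytest

from esskit import CanonicalKmerSet, extract_kmers
from esskit.simdata import SimConfig, random_genome, simulate_reads


def random_kmer_set(seed: int, k: int | None = None, min_len: int = 40,
                    max_len: int = 300) -> CanonicalKmerSet | None:
    """A small seeded k-mer set from one or two random genomes.

    Returns None when the draw produces too few k-mers to be interesting.
    """
    rng = random.Random(seed)
    if k is None:
        k = rng.choice([5, 7, 9, 11, 13])
    seqs = [random_genome(rng.randrange(min_len, max_len), seed * 31 + i) for i in
            range(rng.choice([1, 1, 2]))]
    K = extract_kmers(seqs, k)
    return K if len(K) >= 3 else None


def noisy_kmer_set(seed: int, k: int = 15, genome_length: int = 2_000) -> CanonicalKmerSet:
    """K-mers of simulated error-bearing reads: graphs rich in tips and branches."""
    genome = random_genome(genome_length, seed)
    cfg = SimConfig(genome_length=genome_length, read_length=80, coverage=8.0,
                    error_rate=0.02, seed=seed)
    return extract_kmers(simulate_reads(genome, cfg), k)


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation paths they check)

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc_oracle(x: str) -> str:
    return "".join(_RC[c] for c in reversed(x))


def orient_oracle(x: str, s: int) -> str:
    return x if s == 0 else rc_oracle(x)


def overlap_oracle(x0: str, s0: int, x1: str, s1: int, k: int) -> bool:
    return orient_oracle(x0, 1 - s0)[-(k - 1):] == orient_oracle(x1, s1)[: k - 1]


def brute_force_edges(labels: list[str], k: int) -> set[frozenset]:
    """All bidirected edges by checking every pair and side combination."""
    out = set()
    for x0, x1 in itertools.combinations_with_replacement(sorted(labels), 2):
        for s0, s1 in itertools.product((0, 1), repeat=2):
            if overlap_oracle(x0, s0, x1, s1, k):
                out.add(frozenset({(x0, s0), (x1, s1)}))
    return out


def brute_force_min_cover(graph) -> int:
    """Minimum number of paths in any vertex-disjoint path cover (tiny graphs).

    A cover corresponds to a subset of non-loop edges with at most one edge
    per vertex side and no cycles; |paths| = |V| - |chosen edges|.
    """
    from esskit.bidigraph import is_loop

    edges = [e for e in graph.edges if not is_loop(e)]
    n = len(graph.vertices)
    assert len(edges) <= 16, "oracle is exponential in the edge count"
    best = 0
    for mask in range(1 << len(edges)):
        chosen = [e for i, e in enumerate(edges) if mask >> i & 1]
        side_use: set = set()
        ok = True
        for e in chosen:
            for vs in sorted(e):
                if vs in side_use:
                    ok = False
                    break
                side_use.add(vs)
            if not ok:
                break
        if not ok:
            continue
        # acyclicity via union-find on vertices
        parent = {v: v for v in graph.vertices}

        def find(v):
            while parent[v] != v:
                v = parent[v]
            return v

        for e in chosen:
            (a, _), (b, _) = sorted(e)
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if ok:
            best = max(best, len(chosen))
    return n - best


def brute_force_max_out_forest(nodes: list, arcs: set[tuple]) -> tuple[int, int]:
    """(max edges, min trees) over all spanning out-forests, by enumerating
    parent functions (each node picks an in-neighbor or None) and rejecting
    cyclic assignments."""
    in_nbrs = {v: [None] + sorted(u for (u, w) in arcs if w == v and u != v)
               for v in nodes}
    best_edges = -1
    for choice in itertools.product(*(in_nbrs[v] for v in nodes)):
        parent = dict(zip(nodes, choice))
        ok = True
        for v in nodes:
            seen = set()
            while v is not None:
                if v in seen:
                    ok = False
                    break
                seen.add(v)
                v = parent[v]
            if not ok:
                break
        if ok:
            best_edges = max(best_edges, sum(1 for p in choice if p is not None))
    return best_edges, len(nodes) - best_edges


@pytest.fixture(scope="session")
def fixtures():
    from esskit.simdata import fixture_graphs

    return fixture_graphs()
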