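# Methods

## Model

The input is a set K of canonical k-mers (each the lexicographic minimum of
itself and its reverse complement). The node-centric bidirected de Bruijn
graph dBG(K) has one two-sided vertex per canonical k-mer and an edge for
every oriented (k-1)-overlap between labels: writing `orient(x, s)` for x
(s=0) or its reverse complement (s=1), the edge `{(u0,s0),(u1,s1)}` exists iff
`suf(orient(lab(u0), 1-s0)) = pre(orient(lab(u1), s1))`, with suf/pre taking
k-1 characters. This includes self-overlap loops: homopolymer-like loops
joining the two sides of one vertex, and palindromic-junction loops
`{(u,s),(u,s)}` when a (k-1)-junction word is its own reverse complement
(possible because k-1 is even). Maximal non-branching paths (unitigs) are
compacted into cdBG(K); loops block unitig extension, so a palindromic
junction ends a unitig even if the side has only that loop besides the chain
edge. Compaction rebuilds overlap closure on the unitig spellings, which is
exact: an end-to-end (k-1) match between spellings is precisely an overlap
between their terminal k-mers.

Orientation convention used throughout: an occurrence of vertex u with flag o
is `orient(lab(u), o)`; it enters through side o and exits through side 1-o,
so a path step sequence uses the edge `{(u_{i-1}, 1-o_{i-1}), (u_i, o_i)}`
between consecutive steps and consecutive occurrences overlap by k-1
characters. Flipping a path reverse-complements its spelling.

k is restricted to odd values ≥ 3 so no k-mer equals its own reverse
complement and the canonical set is well defined.

## Path cover and weights

A vertex-disjoint path cover Ψ of cdBG(K) spells an SPSS of weight
`|K| + |Ψ|(k-1)`; this identity is asserted on every cover the package
produces. The greedy cover scans non-loop edges in lexicographic order of
their endpoint (label, side) pairs and merges two distinct paths whenever the
edge joins currently-free outer endpoint sides of both, with union-find
preventing cycles. This is deterministic (vertex ids are the canonical labels
themselves), refuses no legal merge, and empirically lands close to the
minimum path count.

Lower bounds: every edge-free vertex side must be a path-endpoint side and
each path exposes exactly two, so each connected component c with d_c
dead-end sides needs at least `max(1, ceil(d_c/2))` paths; summing gives β,
and C is the component count. These feed the representation floor
`|K| + 3β + C(k-4)`. The floor is valid for k > 4 (at k=3 the (k-4) term
changes sign and the inequality can flip, so the internal weight ≥ floor
assertion applies only for k ≥ 5). β here is the dead-end-side bound, which
is weaker than an instance-optimal cover bound; reported gaps between the
achieved weight and the floor are therefore conservative (larger than what a
tighter β would give).

## Absorption

An absorption edge joins an internal vertex of one cover path (parent) to an
endpoint vertex of another (child), attaching at the child occurrence's outer
free side; attachments at the side consumed by the child's first internal
edge are excluded, since the shared (k-1)-mer then lies interior to the
child's spelling and cannot be removed as a prefix. The absorption digraph
D_A keeps one representative arc per ordered (parent, child) pair (smallest
(parent vertex, child vertex, sides) wins). The edge-maximizing spanning
out-forest is found by condensing D_A into strongly connected components,
picking the smallest path id in every source component as a starter, and
running DFS (sorted neighbor order) that initiates each new tree from a
starter: the forest has exactly n_sc trees — the minimum — and hence the
maximum number of arcs.

## Encoding

The child path is always flipped so the absorbed endpoint is its initiator
and the removed (k-1)-mer is its spelling prefix. Geometry: if the absorption
edge attaches at the *back* side of the parent occurrence (side = 1 -
orientation), the shared window is the k-1 characters ending at the
occurrence's last character and equals the child's prefix — marker `+`. If it
attaches at the *front* side, the window starts at the occurrence's first
character and equals the reverse complement of the child's prefix — marker
`-`. (A suffix-replacement arrangement of the front case is equivalent; the
flipped-prefix form is used because the decoder's single rule then inverts
both cases.) The bracket group `[marker + rest-of-child]` is spliced
immediately after the window; several children at one splice point become
consecutive groups ordered by child path id, all correctly served by the
decoder's "rightmost k-1 outer characters" rule since brackets are not outer.
Splice indices always lie at ≥ k-1 in spelling coordinates (the window itself
precedes them), and for absorbed parents the own-prefix marker substitution
(applied last) never collides with a splice. If the shared window is a
reverse-complement palindrome both markers decode identically and `+` is
chosen. Assembly is bottom-up over the forest and decoding uses an explicit
stack, so absorption chains of any depth are handled without recursion
limits.

Per-path accounting: a root contributes its full spelling length; an
absorbed path contributes `|spell| - (k-1) + 3`. Summing gives
`weight = |K| + 3|Ψ| + n_sc(k-4)`, which the encoder asserts on every run,
along with: number of output strings = n_sc, marker count = |Ψ| - n_sc, and
weight ≥ floor (k ≥ 5). Note the savings per absorption, k-4, is positive
only for k > 4; k=3 inputs are still encoded correctly but may exceed their
SPSS weight.

## Tip mode

Dead-end unitigs get singleton paths; the rest of the graph is covered
greedily. Each tip is absorbed directly into a neighboring non-tip path, so
the forest depth is ≤ 2, brackets never nest, and groups carry no marker:
`[overhang]` decodes by prepending the k-1 outer characters left of the
bracket. A marker-free group can only encode a *back*-side attachment (the
front case would need the shared window as a suffix of some orientation of
the child, which only a marker or a suffix-side bracket rule could express);
tips whose only attachments are front-side therefore remain their own roots,
as do tips with no non-tip neighbor. In a bidirected chain the two tips
attach at opposite parent sides, so exactly one is absorbed for any fixed
parent orientation. Each absorption trades k-1 characters for 2; the weight
is checked against `|K| + |Ψ|(k-1) - (k-3)·(#absorbed)` by direct accounting.

## Degenerate inputs and tie-breaks

- Perfect-cycle components are broken at the lexicographically smallest
  vertex, walking the direction with the smaller spelling.
- Unitigs and cover paths are flip-normalized (canonical spelling / smaller
  endpoint label) so all outputs are deterministic without seeds.
- Ambiguous bases split input sequences into ACGT-only runs; windows spanning
  them are skipped, as k-mer counters conventionally do.
- Counting is exact and in-memory; the package targets desk-scale inputs
  (up to a few hundred thousand distinct k-mers comfortably).

## Synthetic data

The simulator draws a uniform i.i.d. genome, then
`ceil(coverage·|genome|/read_length)` reads at uniform starts, each strand
with probability 1/2, with i.i.d. substitution errors (defaults: 100 kb
genome, 100 bp reads, coverage 10, 1% errors — a scaled-down stand-in for a
small sequencing experiment). Substitution errors are what create dead-end
tips and bubbles, which is the graph structure the absorption machinery
exploits; the simulator deliberately omits indels, quality strings, paired
ends, and non-uniform coverage, so passing tests demonstrate correctness and
the expected compression *ordering* (enriched < tip < plain unitigs in
chars/k-mer) on tip-rich graphs, not the exact compression ratios of any real
dataset. Hand-built fixtures (injected covers and forests, bypassing the
greedy heuristics) pin down the printed encodings `TCGT[+AA]T` and
`AAACC[+G[+T]]`, a mutual-absorption 2-cycle, a palindromic-junction unitig
chain with two tips, a mixed-side star, isolated vertices, and a perfect
cycle component.

## Known limitations

- The dead-end β can undershoot the true minimum cover size (e.g. a star
  with all leaves on one side), so the reported lower-bound gap overstates
  the distance to optimal.
- Exact string-level parity with other implementations of this scheme is not
  a goal; set-level equality of the recovered k-mers is the contract, since
  unitig orientation, cycle breaking, and cover tie-breaks are
  convention-dependent.
- Single-threaded, in-memory; no external-memory k-mer counting or
  compaction.
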