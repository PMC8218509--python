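# esskit

Lossless disk compression of k-mer sets via enriched string sets.

K-mer based tools (assembly, metagenomics, genotyping, database search)
routinely need to store very large sets of canonical k-mers on disk. Writing
one k-mer per line wastes nearly k characters per k-mer, because consecutive
k-mers share (k-1)-mers. A *spectrum-preserving string set* (SPSS) removes
much of that redundancy by gluing k-mers into longer strings: a vertex-disjoint
path cover Ψ of the compacted de Bruijn graph cdBG(K) spells an SPSS of weight

    weight = |K| + |Ψ|·(k-1)

`esskit` goes further. A cover path can still carry a duplicate (k-1)-mer at
its end whenever a neighboring path branches off it. Such a path is *absorbed*:
its redundant (k-1)-mer prefix is replaced by a one-character marker and the
whole path is spliced, in brackets, into its parent's string, giving strings
over the alphabet `{A,C,G,T,[,],+,-}`. `+` stands for the k-1 characters
before the opening bracket, `-` for their reverse complement. For
K = {ACG, CGT, CGA} the representation is `ACG[+A]T`: expanding the marker
gives `ACG[CGA]T`, and cleaving the bracketed string yields `ACGT` and `CGA`.

Absorptions are chosen along a maximum-edge spanning out-forest of the
*absorption digraph* (paths as nodes, parent→child arcs), found via its
strongly-connected-component condensation: the forest has exactly `n_sc`
trees, one per source component, which is provably optimal. Each absorption
trades k-1 nucleotides for 3 characters, so the final weight is exactly

    weight = |K| + 3·|Ψ| + n_sc·(k-4)

and can never go below `|K| + 3·β + C·(k-4)`, where β lower-bounds any
cover's path count and C counts connected components. A simpler *tip mode*
absorbs only dead-end unitigs (typically sequencing-error tips) into their
neighbors with 2 characters per absorption and no markers or nested brackets,
trading some compression for a shallower, faster decode. A recursive decoder
recovers the exact k-mer set in both modes.

## Worked example

```python
>>> import esskit as E
>>> K = E.extract_kmers(["TCGTT", "GTAA"], k=3)
>>> sorted(K.kmers)
['AAC', 'ACG', 'CGA', 'GTA', 'TAA']
>>> r = E.ess_compress(K)
>>> r.strings, r.weight
(('TCGTAAC',), 7)
>>> from esskit.decoder import decode_result
>>> sorted(E.spss_to_kmers(decode_result(r)).kmers) == sorted(K.kmers)
True
```

Five 3-mers stored in 7 characters (1.4 chars/k-mer) instead of 15, and the
decoder recovers the set exactly. On realistic data the pipeline runs from the
command line:

```sh
esskit simulate -o reads.fa --length 100000 --coverage 10 --error-rate 0.01 --seed 1
esskit compress reads.fa -o out.ess --k 21
esskit decompress out.ess -o spss.fa --kmers-out order.txt
esskit validate out.ess kmers.txt
```

`compress` prints a stats JSON; on the simulated dataset above it reports
249,093 distinct 21-mers packed into weight 294,544 (1.18 chars/k-mer, vs
2.65 for plain unitigs and 1.51 for tip mode), with `weight` equal to
`predicted_weight` — the output size matches the closed-form identity — and
`lower_bound` giving the β/C floor. `--mode tip` selects the shallow variant,
`--compress-with gzip|xz` additionally wraps the output in a generic
compressor, and `--counts-out` writes per-k-mer abundances in the exact k-mer
order of the compressed representation, so associated values can be stored
and co-compressed alongside (`decompress --kmers-out` reproduces that order).

## Layout

- `src/esskit/kmerset.py` — canonical k-mers, counting, FASTA/FASTQ and list I/O
- `src/esskit/bidigraph.py` — bidirected DNA graphs, unitigs, compaction
- `src/esskit/pathcover.py` — greedy path cover, SPSS spelling, lower bounds
- `src/esskit/absorption.py` — absorption digraph, SCC condensation, out-forest
- `src/esskit/encoder.py` / `decoder.py` — enriched-string codec and file format
- `src/esskit/tipmode.py` — the dead-end-only variant
- `src/esskit/simdata.py` — seeded genome/read simulator and graph fixtures
- `src/esskit/cli.py` — `esskit` command-line interface
- `docs/methods.md` — model, conventions, and design notes
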