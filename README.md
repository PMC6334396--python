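# seedspan

A parallel, BLAT-style spliced DNA/RNA-to-genome aligner in Python, built
around one guarantee: **output bytes are identical no matter how many
workers, threads, or emulated cluster nodes you run it on.**

## Who this is for

Long transcript and long-read sequences (cDNAs, full-length isoform reads,
nanopore-like noisy reads) cannot be mapped by short-read aligners: they
span exon–intron boundaries and, for noisy reads, carry abundant
mismatches and indels. Seed-and-extend spliced aligners handle them, but a
naive way to parallelize one — running many independent instances over
pieces of the input — loads one genome copy *per process* and scrambles
output order. seedspan implements the alternative architecture: the query
file is *virtually* partitioned into equal-count parts, every worker
shares a single read-only genome index, each worker writes its own
temporary output, and a final merge concatenates them in part order. The
result is bitwise equal to a serial run, while memory stays flat in the
worker count.

## The algorithm

**Index.** The genome is tiled into non-overlapping k-mers (default
k = 11, step 11); each N-free tile maps to its (target, offset) positions.
Tiles occurring more than `oocCutoff` (1024) times are dropped entirely,
keeping lookups deterministic. The index lives in flat numpy arrays so
forked workers share it copy-on-write.

**Per query** (both strands): every overlapping query k-mer is looked up
(seeds); seeds on one target within a narrow diagonal band (`diagSlack`)
form clumps; clumps with at least `minSeeds` hits survive, and clumps
within intron reach of each other are joined. Each seed is extended
ungapped under an x-drop rule, and the extended segments are stitched by
an exact sparse dynamic program with scores

```
match +1   mismatch −1   gap opening −1   intron −1 (gap bases free)
```

where a target-side gap of `minIntron`–`maxIntron` bases (30–750 000) is
an intron and a gap of at most `maxGap` (3) bases is an indel. Every exon
block of a reported chain contains at least one indexed exact tile.
Alignments are reported in PSL (21 tab-separated columns, 0-based
half-open coordinates), best score first, after `minScore` / `minIdentity`
filtering; identity is `100·matches/(matches+misMatches+qBaseInsert)`.

The same cost model is implemented twice: once by the production
seed–clump–extend–stitch path, and once as an exhaustive quadratic DP
(`seedspan.oracle`) that searches every cell of the alignment matrix. The
test suite asserts the two agree exactly on hundreds of random spliced
instances.

## Worked example

Generate a small synthetic genome with 20 spliced genes and map the
transcripts back:

```python
from seedspan.synthetic_data import SynthConfig, gen_genome, gen_transcripts, write_fasta
cfg = SynthConfig(seed=42, genome_length=200_000, n_targets=1, n_genes=20)
genome = gen_genome(cfg)
pairs = gen_transcripts(genome, cfg)          # 9 transcripts pass the 1-5 kb filter
write_fasta(genome.targets, "genome.fa")
write_fasta([r for r, _ in pairs], "transcripts.fa")
```

```
$ seedspan genome.fa transcripts.fa out.psl -threads=4
INFO loaded 9 queries, 1 target sequences
INFO chunk plan: 4 part(s), sizes 3,2,2,2
INFO part 0 finished
...
INFO wrote 9 alignments to out.psl
```

The first data line of `out.psl`:

```
1369  0  0  0  0  0  0  0  -  tx0000  1369  0  1369  chr1  200000  190504  198726  5  158,375,209,344,283,  0,158,533,742,1086,  190504,192807,193898,195833,198443,
```

reads: 1369 matching bases, no mismatches or gaps, minus strand; the
1369-base transcript `tx0000` aligns to `chr1:190504-198726` in 5 blocks —
its five exons — whose sizes, query starts and target starts are the three
comma-separated lists. The gaps between consecutive target blocks are the
introns. Re-running with `-threads=1` or `-nodes=3` produces a
byte-identical file.

The same command shape works for real FASTA files; `-threads=N` is the
only flag you need beyond the classic positional `database query output`
invocation, and `seedspan -help` lists the rest (`-minIdentity`,
`-maxIntron`, `-noHead`, ...). For high-error long reads use
`AlignParams.for_noisy_reads()` in the API, or `-minIdentity=70
-stepSize=5` on the command line.

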