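# Methods

## Scope and shape

seedspan maps DNA/RNA query sequences (spliced transcripts, long noisy
reads) to a reference genome and parallelizes the work at the data level:
whole queries are distributed across workers that each run the full
algorithm against one shared genome index. The package deliberately
excludes protein and translated alignment modes, binary genome formats,
network server modes, repeat masking, and splice-site (GT–AG) consensus
refinement; intron placement is purely score-optimal.

## Alignment model

An alignment is a chain of gap-free blocks, increasing in both query and
target. Between consecutive blocks, the query may skip up to `maxGap`
bases, and the target may skip either up to `maxGap` bases (an indel) or
`minIntron`–`maxIntron` bases (an intron). Scoring: match +1, mismatch −1,
each gapped junction side −1, each intron −1; skipped bases are free;
columns whose target base is N score 0 and are reported in `nCount`.
Charging an intron one gap opening keeps distant spurious blocks from
attaching to a chain for free. In the emitted PSL, intron gaps are *not*
counted in `tNumInsert`/`tBaseInsert` (they are structure, not error);
`repMatches` is always 0 because no repeat-masking logic exists.

A chain is reportable only if every block contains at least one exact
`tileSize`-mer present in the genome index — the search space a
seed-driven aligner can actually reach — and must pass `minScore` (30) and
`minIdentity` (90), with identity defined as
`100·matches/(matches+misMatches+qBaseInsert)`. This simple identity is
*not* the percent-identity of the classic tool family (which discounts
gaps logarithmically); 90 under this formula is considerably stricter.
The `for_noisy_reads()` preset (identity 70, index step 5) is the
calibrated equivalent for ~12%-error reads: at that error rate a
perfectly placed read realizes identity near 80, and a sparser index
would leave seeds so far apart that indel-shifted regions get aligned
through as mismatch runs instead of being taken as short gaps.

### Search procedure

1. **Seeding.** Every overlapping k-mer of the strand-oriented query is
   looked up in the tile index (forward strand only is indexed; minus
   strand alignment reverse-complements the query, halving index memory).
2. **Clumping.** Hits sorted by (target, diagonal, offset) are grouped
   greedily: a hit joins the current clump if it shares the target, lies
   within `diagSlack` (100) of the clump's running median diagonal, and is
   within `clumpGapMax` (100 000) of the clump span. Clumps smaller than
   `minSeeds` (2) are discarded — the main spurious-hit filter. Because an
   intron shifts the diagonal by its full length, each exon forms its own
   clump; surviving same-target clumps within `maxIntron` of each other
   are then merged, and stitching operates on the merged clump.
3. **Extension.** Each seed is extended ungapped in both directions under
   an x-drop rule (`xDrop` = 10). The extension's *scanned extent* runs to
   a drop of `xDrop + tileSize`: crossing a score valley is worthwhile
   whenever a seeded continuation (worth at least a full tile of matches)
   lies beyond it, and the chain DP — not the extension — decides where
   alignments end, so extension errs toward exposing cells. Same-diagonal
   extents separated by fewer than 200 columns are joined for the same
   reason. Duplicate extents from seeds inside already-scanned regions
   are skipped.
4. **Stitching.** An exact dynamic program over the extent cells finds
   the maximum-score chain under the model above, tracking per cell
   whether the current block already contains an indexed tile (so only
   seeded blocks can be left through a junction). Intron-range
   predecessors are found with per-row prefix maxima. Ties are broken
   deterministically (diagonal continuation over junctions, then fixed
   enumeration order), which the byte-identity guarantee requires.

### Reference implementation

`seedspan.oracle` implements the identical cost model as a dense
quadratic DP over every cell of the query × target matrix, vectorized per
row, with the same seeded-block bookkeeping. It is independent of
seeding, clumping and extension, usable up to a few hundred by a few
thousand bases, and requires `maxIntron ≥ target length` (its intron
lookback uses full prefix maxima). Tests and the acceptance script assert
that the production path attains the oracle's optimum on random planted
instances (substitutions ~3%, indels ~0.5% of 1–2 bases, half the
instances spliced, some decoys). Agreement is exact on all tested
instances; it is not a theorem — a valley deeper than `xDrop + tileSize`
in front of a large gain could still hide cells from the sparse DP — but
no such case arises at these error rates.

## Parallel execution

`plan_chunks(n, w)` partitions n queries into `min(w, max(n, 1))`
contiguous ordinal ranges whose lengths differ by at most one, remainder
to the leading parts. Partitioning is virtual — ranges over one parsed
query list, no file splitting. Workers process their range in ordinal
order into per-part temporary files; the merge concatenates them in part
index order and deletes them, emitting the optional 5-line PSL header at
most once. Because `align_query` is a pure function and the merge order
is fixed, output bytes are invariant over worker count — the property the
whole design serves, asserted directly by the tests.

Two worker mechanisms satisfy the same contract. **Processes** (default):
forked children inherit the genome and index, which live in flat numpy
buffers shared copy-on-write, so no worker ever holds a second copy of
the data; this is the mechanism that converts cores into wall-clock
speedup. **Threads**: one address space, the closest analog of a
pthread-style design; under the interpreter lock threads provide no
speedup for this CPU-bound work, but they demonstrate the shared-memory
contract exactly, and the memory assertions use them. Peak memory is
measured as the summed proportional set size (PSS) of the worker tree
sampled from `/proc`, which attributes shared pages fractionally — a
worker that duplicated the index would be visible in full.

The speedup check is stated relative to the hardware: with ≥4 CPUs
available, 4 workers must finish in under 0.8× the serial wall clock;
with a single CPU no speedup is possible and the meaningful property is
that parallel overhead stays well below the worker-count multiple a
broken sharing design would cost; the test asserts that bound there.

Cluster mode emulates a master/node/thread scatter-gather on one machine:
queries are split equal-count across nodes, each node (an OS process)
runs the parallel engine on its slice, and the master concatenates node
outputs in node order. Output is therefore byte-identical across all
(nodes × threads) topologies, including 1×1. Node assignment is static in
rank order; the identity contract makes the assignment unobservable in
the output. A real MPI launcher could stand behind the same `NodePlan`
without changing output; network transport is out of scope.

## Synthetic data

The generator produces the two study corpora with exact ground truth.

**Standard corpus** (defaults): 1 Mb genome over 2 targets, GC 0.45, 150
genes of 3–8 exons × 80–400 bp with introns drawn log-uniformly from
50–5000 bp, transcripts spliced (reverse-complemented for minus-strand
genes) and filtered to 1–5 kb, leaving ~100–110 transcripts. Log-uniform
intron lengths are both the realistic heavy-tailed shape and the only one
under which 150 multi-exon genes fit 1 Mb without overlap. Genes never
overlap on the same strand; opposite-strand overlap is allowed and leaves
truth unambiguous because recovery scoring is strand-aware. Intron
endpoints are locally adjusted (by at most 15 bases) so that no exon
junction admits an equal-scoring shifted placement — real aligners
disambiguate such junctions with splice-site consensus, which this
aligner deliberately lacks, so the generator removes the ambiguity
instead; without this, score-equivalent boundary shifts (possible at
roughly 40% of random junctions) would make "exact boundary recovery"
ill-posed.

**Nanopore-like corpus**: the same gene models, fragmented to log-normal
lengths matching mean 1868 / median 1787 bases (capped by transcript
length, floor 200), then corrupted i.i.d. per base with 6% substitutions,
3% insertions, 3% deletions — 12% total error. The i.i.d. model has no
homopolymer bias or quality structure; passing tests on it shows
tolerance of abundant uniform errors, not of real nanopore error
profiles.

Every artifact is a pure function of the configuration (seed included;
independent numbered substreams for genome, gene placement, and errors).

**Recovery scoring.** The top hit of a read is its first output record
(records are emitted best-score-first per query). It recovers the locus
if it is on the true target and strand and at least half of its aligned
target bases fall inside the true gene span — base-level overlap, because
a single distant spurious block joined by an intron-scale jump could
stretch the span envelope arbitrarily without making the placement
wrong. Boundary recall is the fraction of true exon endpoints appearing
exactly as block boundaries of the top hit.

## Problem sizes

The test suite and acceptance script run the full standard corpus
(~100 transcripts against 1 Mb) for identity, recovery and memory checks;
500 oracle-comparison instances (queries ≤ 200 bp, targets 2 kb); an
exhaustive planner sweep (all n ≤ 200, parts ≤ 16); and a doubled corpus
(~200 queries) for the wall-clock comparison. These sizes keep a complete
run in the low minutes on one core while leaving every measured rate at
sample sizes (≥ 100 reads, ≥ 1000 boundaries) where the acceptance margins
are meaningful.

## Known limitations

* No splice-site consensus: intron boundaries are score-optimal only, the
  largest fidelity gap versus the classic tool family.
* Identity filtering uses the simple formula above; thresholds are not
  interchangeable with tools using log-discounted gap penalties.
* The sparse chain DP equals the exhaustive optimum empirically, not
  provably, beyond the `xDrop + tileSize` valley depth.
* Overused tiles are dropped, not sampled: extremely repetitive regions
  are invisible to seeding by design (determinism over sensitivity).
* The error model and gene placement simplifications mean recovery rates
  here bound idealized, not real-data, performance.
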