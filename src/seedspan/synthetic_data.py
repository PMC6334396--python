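"""Synthetic genomes, gene models, spliced transcripts and noisy long reads.

The generator emulates the two evaluation regimes the aligner is built
for: clean spliced transcripts in the 1-5 kb range, and nanopore-like
long reads with abundant mismatches and indels (about 12% total error,
length distribution centered near 1.9 kb).  Every artifact is a pure
function of :class:`SynthConfig` — the seed is part of the config — so
corpora are reproducible by construction.

A few deliberate departures from real data keep the ground truth
unambiguous (and feasible) for recovery scoring:

* genes on the same strand never overlap, so each read has exactly one
  true locus (locus scoring is strand-aware, so opposite-strand overlap
  does not create ambiguity);
* intron lengths are drawn log-uniformly from their range — the
  heavy-tailed shape real intron length distributions have, and the only
  shape under which 150 multi-exon genes fit a 1 Mb genome;
* intron endpoints are resampled so that no exon junction can be shifted
  to an equal-scoring alternative placement (real aligners disambiguate
  such junctions with splice-site consensus, which this aligner does not
  model).

The error process is i.i.d. per base with no homopolymer bias — the
simplest model producing abundant mismatches and gaps; real nanopore
error profiles are more structured.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .aligner_core import revcomp
from .genome_index import Genome
from .seq_io import PslRecord, SequenceRecord

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "gen_genome",
    "gen_transcripts",
    "corrupt_reads",
    "ont_corpus",
    "evaluate_recovery",
    "RecoveryStats",
    "gen_score_instances",
    "write_fasta",
    "write_truth_tsv",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SynthConfig:
    """Generator configuration; defaults are the standard synthetic corpus
    (1 Mb genome over 2 targets, 150 genes, exons 3-8 x 80-400 bp, introns
    50-5000 bp, transcripts filtered to 1-5 kb).  The nanopore-like corpus
    uses the same gene models with error_rates (0.06, 0.03, 0.03) and
    fragment lengths log-normal around mean 1868 / median 1787 bases."""

    seed: int = 1234
    genome_length: int = 1_000_000
    n_targets: int = 2
    gc_content: float = 0.45
    n_genes: int = 150
    exons_per_gene: Tuple[int, int] = (3, 8)
    exon_length: Tuple[int, int] = (80, 400)
    intron_length: Tuple[int, int] = (50, 5000)
    transcript_length_range: Tuple[int, int] = (1000, 5000)
    error_rates: Tuple[float, float, float] = (0.0, 0.0, 0.0)  # mismatch, ins, del
    read_length_stats: Optional[Tuple[int, int]] = None  # (mean, median)

    def __post_init__(self) -> None:
        if not all(0.0 <= r < 1.0 for r in self.error_rates):
            raise ValueError("error rates must be in [0, 1)")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")
        if self.intron_length[0] < 30:
            raise ValueError("minimum intron length must be >= 30")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "SynthConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in (
            "exons_per_gene", "exon_length", "intron_length",
            "transcript_length_range", "error_rates", "read_length_stats",
        ):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class SynthTruth:
    """Ground truth for one read: its gene, locus and exon structure."""

    read_name: str
    gene_id: str
    target: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]  # sorted, non-overlapping target intervals

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def gen_genome(config: SynthConfig) -> Genome:
    """I.i.d. genome with the configured GC content, split evenly into
    ``n_targets`` records named chr1, chr2, ..."""
    rng = _rng(config, 0)
    at = (1.0 - config.gc_content) / 2.0
    gc = config.gc_content / 2.0
    per = config.genome_length // config.n_targets
    targets = []
    for i in range(config.n_targets):
        length = per if i < config.n_targets - 1 else config.genome_length - per * (
            config.n_targets - 1
        )
        draws = rng.choice(4, size=length, p=[at, gc, gc, at])
        residues = "".join(_BASES[draws])
        targets.append(
            SequenceRecord(name=f"chr{i + 1}", description="", residues=residues,
                           ordinal=i)
        )
    return Genome(targets)


def _unambiguous_intron(seq: str, b_prev: int, intron_len: int, exon_len: int,
                        tlen: int) -> Optional[int]:
    """Pick an intron length >= intron_len such that the junction admits no
    equal-scoring shifted placement; returns the adjusted length or None."""
    for extra in range(0, 16):
        L = intron_len + extra
        a_next = b_prev + L
        if a_next + exon_len > tlen:
            return None
        # shift right blocked: genome base after the exon differs from the
        # first base of the next exon; shift left blocked symmetrically.
        if seq[b_prev] != seq[a_next] and seq[a_next - 1] != seq[b_prev - 1]:
            return L
    return None


def gen_transcripts(
    genome: Genome, config: SynthConfig
) -> List[Tuple[SequenceRecord, SynthTruth]]:
    """Place non-overlapping genes, splice their exons into transcripts,
    and keep those within the configured length range.

    Raises RuntimeError (advising a larger genome) if a gene cannot be
    placed after bounded retries.
    """
    rng = _rng(config, 1)
    occupied: Dict[Tuple[int, str], List[Tuple[int, int]]] = {
        (i, s): [] for i in range(len(genome)) for s in "+-"
    }
    out: List[Tuple[SequenceRecord, SynthTruth]] = []
    ordinal = 0
    for gid in range(config.n_genes):
        placed = False
        for _attempt in range(200):
            tid = int(rng.integers(0, len(genome)))
            seq = genome.targets[tid].residues
            tlen = len(seq)
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(config.exons_per_gene[0],
                                       config.exons_per_gene[1] + 1))
            exon_lens = [
                int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
                for _ in range(n_exons)
            ]
            lo_i, hi_i = config.intron_length
            intron_lens = [
                int(round(math.exp(rng.uniform(math.log(lo_i), math.log(hi_i)))))
                for _ in range(n_exons - 1)
            ]
            span_max = sum(exon_lens) + sum(intron_lens) + 16 * max(n_exons - 1, 1)
            if span_max >= tlen:
                continue
            start = int(rng.integers(0, tlen - span_max))
            exons: List[Tuple[int, int]] = [(start, start + exon_lens[0])]
            ok = True
            for i in range(1, n_exons):
                b_prev = exons[-1][1]
                L = _unambiguous_intron(seq, b_prev, intron_lens[i - 1],
                                        exon_lens[i], tlen)
                if L is None:
                    ok = False
                    break
                a = b_prev + L
                exons.append((a, a + exon_lens[i]))
            if not ok:
                continue
            gene_span = (exons[0][0], exons[-1][1])
            if any(
                not (gene_span[1] <= s or e <= gene_span[0])
                for (s, e) in occupied[(tid, strand)]
            ):
                continue
            occupied[(tid, strand)].append(gene_span)
            spliced = "".join(seq[a:b] for a, b in exons)
            if strand == "-":
                spliced = revcomp(spliced)
            name = f"tx{gid:04d}"
            lo, hi = config.transcript_length_range
            if lo <= len(spliced) <= hi:
                rec = SequenceRecord(name=name, description=f"gene{gid:04d}",
                                     residues=spliced, ordinal=ordinal)
                truth = SynthTruth(
                    read_name=name, gene_id=f"gene{gid:04d}",
                    target=genome.names[tid], strand=strand, exons=tuple(exons),
                )
                out.append((rec, truth))
                ordinal += 1
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place gene {gid} after 200 attempts; "
                "use a larger genome or fewer/smaller genes"
            )
    return out


def corrupt_reads(
    transcripts: Sequence[SequenceRecord], config: SynthConfig
) -> List[SequenceRecord]:
    """Apply the i.i.d. per-base error model to each sequence.

    Per base: deletion at the deletion rate; otherwise substitution (to a
    uniform different base) at the mismatch rate; and, independently,
    insertion of a uniform base after it at the insertion rate.  Read
    names get a ``_read`` suffix so the original transcript (and through
    it the ground truth) stays linked.  Reads that would come out empty
    are dropped.
    """
    p_mis, p_ins, p_del = config.error_rates
    rng = _rng(config, 2)
    out: List[SequenceRecord] = []
    ordinal = 0
    for rec in transcripts:
        res = _corrupt_residues(rec.residues, p_mis, p_ins, p_del, rng)
        if not res:
            continue
        out.append(
            SequenceRecord(name=rec.name + "_read", description=rec.description,
                           residues=res, ordinal=ordinal)
        )
        ordinal += 1
    return out


def _corrupt_residues(
    residues: str, p_mis: float, p_ins: float, p_del: float,
    rng: np.random.Generator,
) -> str:
    n = len(residues)
    dels = rng.random(n) < p_del
    subs = rng.random(n) < p_mis
    inss = rng.random(n) < p_ins
    sub_choice = rng.integers(1, 4, size=n)  # offset among the 3 other bases
    ins_choice = rng.integers(0, 4, size=n)
    idx = {b: i for i, b in enumerate("ACGT")}
    chunks: List[str] = []
    for i, base in enumerate(residues):
        if not dels[i]:
            if subs[i] and base in idx:
                chunks.append("ACGT"[(idx[base] + sub_choice[i]) % 4])
            else:
                chunks.append(base)
        if inss[i]:
            chunks.append("ACGT"[ins_choice[i]])
    return "".join(chunks)


def ont_corpus(
    genome: Genome, config: SynthConfig
) -> List[Tuple[SequenceRecord, SynthTruth]]:
    """Nanopore-like corpus: fragment each transcript to a log-normal
    length (mean/median from ``read_length_stats``, when set), then apply
    the error model.  Truth carries the full gene structure; locus
    recovery is scored against the gene span."""
    transcripts = gen_transcripts(genome, config)
    rng = _rng(config, 3)
    p_mis, p_ins, p_del = config.error_rates
    out: List[Tuple[SequenceRecord, SynthTruth]] = []
    ordinal = 0
    for rec, truth in transcripts:
        res = rec.residues
        if config.read_length_stats is not None:
            mean, median = config.read_length_stats
            sigma = math.sqrt(max(2.0 * math.log(mean / median), 1e-9))
            length = int(rng.lognormal(math.log(median), sigma))
            length = max(200, min(length, len(res)))
            start = int(rng.integers(0, len(res) - length + 1))
            res = res[start : start + length]
        res = _corrupt_residues(res, p_mis, p_ins, p_del, rng)
        if not res:
            continue
        read = SequenceRecord(name=rec.name + "_read", description=rec.description,
                              residues=res, ordinal=ordinal)
        out.append(
            (read, SynthTruth(read_name=read.name, gene_id=truth.gene_id,
                              target=truth.target, strand=truth.strand,
                              exons=truth.exons))
        )
        ordinal += 1
    return out


@dataclass
class RecoveryStats:
    n_reads: int
    n_locus_correct: int
    n_boundaries: int
    n_boundaries_recovered: int

    @property
    def locus_rate(self) -> float:
        return self.n_locus_correct / self.n_reads if self.n_reads else 0.0

    @property
    def boundary_recall(self) -> float:
        return (
            self.n_boundaries_recovered / self.n_boundaries
            if self.n_boundaries
            else 0.0
        )


def evaluate_recovery(
    records: Iterable[PslRecord],
    truths: Sequence[SynthTruth],
    min_read_length: int = 0,
    read_lengths: Optional[Dict[str, int]] = None,
) -> RecoveryStats:
    """Score top-hit locus recovery and exact exon-boundary recall.

    The top hit for a read is its first record in the stream (the aligner
    emits each query's alignments best-first, and the parallel merge
    preserves query order).  A top hit recovers the locus when it lies on
    the true target and strand and at least half of its aligned target
    bases (summed over blocks) fall inside the true gene span.  Boundary
    recall counts, over reads scored for boundaries, the fraction of true
    exon endpoints that appear exactly as block boundaries of the top hit.
    """
    top: Dict[str, PslRecord] = {}
    for rec in records:
        if rec.qName not in top:
            top[rec.qName] = rec
    n_reads = n_locus = n_bound = n_bound_hit = 0
    for truth in truths:
        if read_lengths is not None:
            if read_lengths.get(truth.read_name, 0) < min_read_length:
                continue
        n_reads += 1
        rec = top.get(truth.read_name)
        boundaries = [x for (a, b) in truth.exons for x in (a, b)]
        n_bound += len(boundaries)
        if rec is None:
            continue
        span_lo, span_hi = truth.span
        aligned = overlap = 0
        for t0, size in zip(rec.tStarts, rec.blockSizes):
            aligned += size
            overlap += max(0, min(t0 + size, span_hi) - max(t0, span_lo))
        if (
            rec.tName == truth.target
            and rec.strand == truth.strand
            and overlap * 2 >= aligned
        ):
            n_locus += 1
            found = set()
            for t0, size in zip(rec.tStarts, rec.blockSizes):
                found.add(t0)
                found.add(t0 + size)
            n_bound_hit += sum(1 for x in boundaries if x in found)
    return RecoveryStats(n_reads, n_locus, n_bound, n_bound_hit)


def gen_score_instances(
    seed: int,
    n_instances: int,
    target_len: int = 2000,
    query_len: Tuple[int, int] = (60, 200),
    sub_rate: float = 0.03,
    indel_rate: float = 0.005,
    intron_prob: float = 0.5,
    intron_len: Tuple[int, int] = (30, 600),
    decoy_prob: float = 0.05,
) -> List[Tuple[str, str]]:
    """Random (query, target) pairs for score validation against the
    exhaustive DP: a query is a (possibly spliced, possibly reverse
    complemented) substring of the target with substitutions and 1-2 base
    indels, or, with small probability, an unrelated decoy sequence."""
    rng = np.random.default_rng([seed, 17])
    out: List[Tuple[str, str]] = []
    for _ in range(n_instances):
        target = "".join(_BASES[rng.integers(0, 4, size=target_len)])
        qlen = int(rng.integers(query_len[0], query_len[1] + 1))
        if rng.random() < decoy_prob:
            query = "".join(_BASES[rng.integers(0, 4, size=qlen)])
            out.append((query, target))
            continue
        if rng.random() < intron_prob and qlen >= 40:
            e1 = int(rng.integers(20, qlen - 19))
            e2 = qlen - e1
            ilen = int(rng.integers(intron_len[0], intron_len[1] + 1))
            span = qlen + ilen
            start = int(rng.integers(0, max(target_len - span, 1)))
            base = target[start : start + e1] + target[start + e1 + ilen : start + span]
        else:
            start = int(rng.integers(0, max(target_len - qlen, 1)))
            base = target[start : start + qlen]
        query = _corrupt_residues(base, sub_rate, indel_rate, indel_rate, rng)
        if rng.random() < 0.5:
            query = revcomp(query)
        out.append((query, target))
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str, width: int = 70) -> None:
    with open(path, "w", encoding="ascii", newline="") as fh:
        for rec in records:
            header = f">{rec.name}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def write_truth_tsv(truths: Iterable[SynthTruth], path: str) -> None:
    """Tab-separated truth: read, gene, target, strand, comma-joined exon
    intervals (start-end)."""
    with open(path, "w", encoding="ascii", newline="") as fh:
        fh.write("read\tgene\ttarget\tstrand\texons\n")
        for t in truths:
            exons = ",".join(f"{a}-{b}" for a, b in t.exons)
            fh.write(f"{t.read_name}\t{t.gene_id}\t{t.target}\t{t.strand}\t{exons}\n")
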