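import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seedspan.aligner_core import (
    AlignParams,
    SeedHit,
    align_query,
    clump_hits,
    extend_clump,
    merge_clumps,
    psl_score,
    revcomp,
    seed_query,
)
from seedspan.genome_index import Genome, build_index
from seedspan.oracle import oracle_best_score_both_strands
from seedspan.seq_io import SequenceRecord
from seedspan.synthetic_data import gen_score_instances

_BASES = np.array(list("ACGT"))


def _random_seq(rng, n):
    return "".join(_BASES[rng.integers(0, 4, n)])


def _genome(seq, name="chrT"):
    return Genome([SequenceRecord(name, "", seq, 0)])


def _sensitive():
    """Exhaustive-search parameters: every seed kept, no score filtering."""
    return AlignParams(tile_size=11, step_size=1, min_seeds=1, min_score=0,
                      min_identity=0.0)


@pytest.mark.parametrize(
    "seq,expected",
    [("ACGT", "ACGT"), ("AACN", "NGTT"), ("", "")],
)
def test_revcomp_examples(seq, expected):
    assert revcomp(seq) == expected


@given(st.text(alphabet="ACGTN", max_size=60))
def test_revcomp_is_involution(seq):
    assert revcomp(revcomp(seq)) == seq


def test_revcomp_rejects_invalid_residues():
    with pytest.raises(ValueError):
        revcomp("ACGU")


@pytest.fixture(scope="module")
def idx():
    return build_index(_genome("ACGTACGT"), 4, 4, 10)


class TestSeeding:
    def test_small_query_hits_every_table_entry(self, idx):
        hits = seed_query("ACGT", "+", idx)
        assert [(h.q_pos, h.t_pos, h.diag) for h in hits] == [(0, 0, 0), (0, 4, 4)]

    def test_query_with_no_indexed_tile(self, idx):
        assert seed_query("TTTT", "+", idx) == []

    def test_overlapping_tiles_match_bruteforce_enumeration(self, idx):
        query = "ACGTACGT"
        expected = []
        for q_pos in range(len(query) - 4 + 1):
            for t_id, t_pos in idx.lookup(query[q_pos : q_pos + 4]):
                expected.append(SeedHit(q_pos, t_id, t_pos, t_pos - q_pos))
        expected.sort(key=lambda h: (h.t_id, h.diag, h.t_pos))
        hits = seed_query(query, "+", idx)
        assert hits == expected
        assert len(hits) == 4

    def test_query_shorter_than_tile(self, idx):
        assert seed_query("ACG", "+", idx) == []


class TestClumping:
    def test_nearby_diagonals_form_one_clump(self):
        p = AlignParams(min_seeds=2, diag_slack=5)
        hits = [SeedHit(0, 0, 0, 0), SeedHit(1, 0, 2, 1)]
        clumps = clump_hits(hits, p)
        assert len(clumps) == 1 and len(clumps[0].hits) == 2

    def test_different_targets_never_share_a_clump(self):
        p = AlignParams(min_seeds=2)
        hits = sorted(
            [SeedHit(0, 0, 0, 0), SeedHit(0, 1, 0, 0)],
            key=lambda h: (h.t_id, h.diag, h.t_pos),
        )
        assert clump_hits(hits, p) == []

    def test_distant_diagonals_split_and_min_seeds_filters(self):
        hits = [SeedHit(0, 0, 0, 0), SeedHit(0, 0, 1000, 1000)]
        p2 = AlignParams(min_seeds=2, diag_slack=5, clump_gap_max=100)
        assert clump_hits(hits, p2) == []
        p1 = AlignParams(min_seeds=1, diag_slack=5, clump_gap_max=100)
        assert len(clump_hits(hits, p1)) == 2

    def test_merge_joins_exon_clumps_within_intron_reach(self):
        p = AlignParams(min_seeds=1, max_intron=500)
        clumps = clump_hits(
            [SeedHit(0, 0, 100, 100), SeedHit(0, 0, 400, 400), SeedHit(0, 0, 5000, 5000)],
            p,
        )
        merged = merge_clumps(clumps, p)
        assert [len(c.hits) for c in merged] == [2, 1]


@pytest.fixture(scope="module")
def two_exon():
    """Planted two-exon gene: exons [200,260) and [500,560), junction
    bases adjusted so no equal-scoring shifted placement exists."""
    rng = np.random.default_rng(5)
    t = list(_random_seq(rng, 1000))
    if t[260] == t[500]:
        t[260] = "A" if t[500] != "A" else "C"
    if t[499] == t[259]:
        t[499] = "A" if t[259] != "A" else "C"
    tgt = "".join(t)
    query = tgt[200:260] + tgt[500:560]
    return tgt, query


class TestExtension:
    def test_exact_substring_single_block(self):
        rng = np.random.default_rng(0)
        tgt = _random_seq(rng, 400)
        g = _genome(tgt)
        p = _sensitive()
        idx = build_index(g, p.tile_size, p.step_size, p.overused_cutoff)
        rec = align_query(SequenceRecord("q", "", tgt[100:200], 0), g, idx, p)[0]
        assert (rec.matches, rec.misMatches, rec.blockCount) == (100, 0, 1)
        assert (rec.tStart, rec.tEnd, rec.strand) == (100, 200, "+")
        assert psl_score(rec) == 100

    def test_single_central_mismatch_bridged_by_xdrop(self):
        rng = np.random.default_rng(1)
        tgt = _random_seq(rng, 400)
        g = _genome(tgt)
        p = _sensitive()
        idx = build_index(g, p.tile_size, p.step_size, p.overused_cutoff)
        q = list(tgt[100:150])
        q[25] = {"A": "C"}.get(q[25], "A")
        rec = align_query(SequenceRecord("q", "", "".join(q), 0), g, idx, p)[0]
        assert (rec.matches, rec.misMatches) == (49, 1)
        assert psl_score(rec) == 48

    def test_two_exon_transcript_recovers_intron(self, two_exon):
        tgt, query = two_exon
        g = _genome(tgt)
        p = _sensitive()
        idx = build_index(g, p.tile_size, p.step_size, p.overused_cutoff)
        rec = align_query(SequenceRecord("tx", "", query, 0), g, idx, p)[0]
        assert rec.blockCount == 2
        assert rec.blockSizes == [60, 60]
        assert rec.tStarts == [200, 500]
        assert (rec.qNumInsert, rec.tNumInsert) == (0, 0)  # intron is not a gap
        assert rec.matches == 120
        # 240-base target gap is intron-classified and costs one gap opening
        assert psl_score(rec) == 119
        assert psl_score(rec) == oracle_best_score_both_strands(query, tgt, idx, p)

    def test_extend_clump_returns_none_below_min_score(self, two_exon):
        tgt, query = two_exon
        g = _genome(tgt)
        p = AlignParams(tile_size=11, step_size=1, min_seeds=1, min_score=10_000,
                        min_identity=0.0)
        idx = build_index(g, p.tile_size, p.step_size, p.overused_cutoff)
        hits = seed_query(query, "+", idx)
        clump = merge_clumps(clump_hits(hits, p), p)[0]
        assert extend_clump(query, g, idx, clump, p) is None


class TestAlignQuery:
    def test_query_identical_to_short_target(self):
        tgt = "ACGTACGTACGTACGTACGT"
        g = _genome(tgt)
        p = AlignParams(tile_size=4, step_size=4, min_seeds=1, min_score=0,
                        min_identity=0.0, overused_cutoff=1024)
        idx = build_index(g, 4, 4, 1024)
        recs = align_query(SequenceRecord("q", "", tgt, 0), g, idx, p)
        top = recs[0]
        assert top.matches == 20 and top.strand == "+"
        assert (top.qStart, top.qEnd, top.tStart, top.tEnd) == (0, 20, 0, 20)

    def test_reverse_complement_query_maps_minus_strand(self):
        rng = np.random.default_rng(2)
        tgt = _random_seq(rng, 600)
        g = _genome(tgt)
        p = _sensitive()
        idx = build_index(g, p.tile_size, p.step_size, p.overused_cutoff)
        rec = align_query(
            SequenceRecord("q", "", revcomp(tgt[150:250]), 0), g, idx, p
        )[0]
        assert (rec.matches, rec.strand, rec.tStart, rec.tEnd) == (100, "-", 150, 250)

    @pytest.mark.parametrize("seed", [3, 4, 5, 6])
    def test_strand_symmetry(self, seed):
        """align(q) and align(revcomp(q)) give the same alignments up to
        strand flip and query coordinate mirroring."""
        rng = np.random.default_rng(seed)
        tgt = _random_seq(rng, 800)
        g = _genome(tgt)
        p = _sensitive()
        idx = build_index(g, p.tile_size, p.step_size, p.overused_cutoff)
        q = tgt[300:420]
        fwd = align_query(SequenceRecord("q", "", q, 0), g, idx, p)
        rev = align_query(SequenceRecord("q", "", revcomp(q), 0), g, idx, p)

        def canon(recs):
            out = set()
            for r in recs:
                out.add(
                    (r.matches, r.misMatches, r.tName, r.tStart, r.tEnd,
                     r.qStart, r.qEnd, tuple(r.blockSizes), tuple(r.tStarts))
                )
            return out

        flipped = {"+": "-", "-": "+"}
        assert canon(fwd) == canon(rev)
        assert sorted(flipped[r.strand] for r in fwd) == sorted(
            r.strand for r in rev
        )

    def test_align_query_is_deterministic(self, std_genome, std_index, std_corpus):
        reads, _ = std_corpus
        p = AlignParams()
        q = reads[0]
        lines_a = [r.to_line() for r in align_query(q, std_genome, std_index, p)]
        lines_b = [r.to_line() for r in align_query(q, std_genome, std_index, p)]
        assert lines_a == lines_b and lines_a

    def test_query_shorter_than_tile_yields_nothing(self, std_genome, std_index):
        p = AlignParams()
        assert align_query(
            SequenceRecord("tiny", "", "ACGT", 0), std_genome, std_index, p
        ) == []

    def test_emitted_records_satisfy_psl_invariants(self, std_psl_records):
        for rec in std_psl_records:
            rec.validate()


def test_best_scores_match_exhaustive_dp_sample():
    """Spot sample of the oracle-equivalence property (the acceptance
    suite runs the full-size version)."""
    p = _sensitive()
    for query, target in gen_score_instances(seed=99, n_instances=40):
        g = _genome(target)
        idx = build_index(g, p.tile_size, p.step_size, p.overused_cutoff)
        recs = align_query(SequenceRecord("q", "", query, 0), g, idx, p)
        best = max((psl_score(r) for r in recs), default=None)
        assert best == oracle_best_score_both_strands(query, target, idx, p)
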