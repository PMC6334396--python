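"""Per-worker spliced alignment: seed -> diagonal clump -> extend -> stitch.

One query is mapped on both strands by looking up every overlapping query
tile in the shared genome index, grouping hits into diagonal-band clumps,
extending each seed ungapped under an x-drop rule, and chaining the
extended segments with a sparse dynamic program that scores matches +1,
mismatches -1, one point per gap opening, and one point per intron
(target-side gaps of at least ``min_intron`` bases; gap bases themselves
are free).  Chains whose every exon block contains an indexed exact tile
are the search space; the chain DP is exact over the cells the extensions
produce.

Everything here is a pure function of (query, genome, params): no
randomness, no shared mutable state, deterministic tie-breaks.  That is
what makes output bytes identical regardless of how queries are divided
among workers.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .genome_index import Genome, TileIndex, encode_residues
from .seq_io import PslRecord, SequenceRecord

__all__ = [
    "AlignParams",
    "SeedHit",
    "Clump",
    "Alignment",
    "revcomp",
    "seed_query",
    "clump_hits",
    "merge_clumps",
    "extend_clump",
    "align_query",
    "psl_score",
]

_RC = str.maketrans("ACGTN", "TGCAN")
NEG_INF = float("-inf")
# columns of valley tolerated when joining same-diagonal extents
_BRIDGE = 200


def revcomp(residues: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(residues) - set("ACGTN")
    if bad:
        raise ValueError(f"revcomp: invalid residues {sorted(bad)!r}")
    return residues.translate(_RC)[::-1]


@dataclass
class AlignParams:
    """Tunable alignment knobs; all surface on the command line.

    ``min_intron`` must exceed ``max_gap`` so that a target-side gap is
    unambiguously either a small indel or an intron, never both.
    """

    tile_size: int = 11
    step_size: int = 11
    overused_cutoff: int = 1024
    min_seeds: int = 2
    diag_slack: int = 100
    clump_gap_max: int = 100_000
    min_score: int = 30
    min_identity: float = 90.0
    min_intron: int = 30
    max_intron: int = 750_000
    max_gap: int = 3
    x_drop: int = 10

    @classmethod
    def for_noisy_reads(cls, **overrides) -> "AlignParams":
        """Preset for high-error long reads (nanopore-like, ~10-15% error).

        The default identity cutoff of 90 is calibrated to this package's
        simple identity formula, 100 * matches / (matches + misMatches +
        qBaseInsert), under which a read with 12% sequencing error scores
        near 80 even when perfectly placed; 70 admits such reads while
        still rejecting random placements (whose chains stay short and are
        caught by min_score).  A denser index step keeps seeds close
        enough that frequent indels are taken as short gaps instead of
        being aligned through as mismatch runs.
        """
        overrides.setdefault("min_identity", 70.0)
        overrides.setdefault("step_size", 5)
        return cls(**overrides)

    def __post_init__(self) -> None:
        if self.min_intron <= self.max_gap:
            raise ValueError("min_intron must exceed max_gap")
        if self.max_intron <= self.min_intron:
            raise ValueError("max_intron must exceed min_intron")
        if not (4 <= self.tile_size <= 18):
            raise ValueError("tile_size must be in [4, 18]")
        if not (1 <= self.step_size <= self.tile_size):
            raise ValueError("step_size must be in [1, tile_size]")


class SeedHit(NamedTuple):
    q_pos: int   # tile start in strand-oriented query
    t_id: int
    t_pos: int   # tile start in target (forward coordinates)
    diag: int    # t_pos - q_pos


@dataclass
class Clump:
    """Seed hits on one target within a narrow diagonal band."""

    t_id: int
    strand: str
    hits: List[SeedHit]
    diag_lo: int
    diag_hi: int
    t_min: int   # smallest hit t_pos
    t_max: int   # largest hit t_pos + tile_size (exclusive span end)


@dataclass
class Alignment:
    """A blocked, strand-aware, possibly intron-split alignment.

    ``blocks`` are (qStart, tStart, size) triples in strand-oriented query
    coordinates and forward target coordinates.  The score charges one
    point per gap opening and one per intron on top of match/mismatch;
    intron bases are free and are excluded from tNumInsert/tBaseInsert.
    """

    q_name: str
    t_name: str
    t_id: int
    strand: str
    blocks: List[Tuple[int, int, int]]
    matches: int
    mis_matches: int
    n_count: int
    q_num_insert: int
    q_base_insert: int
    t_num_insert: int
    t_base_insert: int
    n_introns: int
    score: int

    @property
    def identity(self) -> float:
        denom = self.matches + self.mis_matches + self.q_base_insert
        return 100.0 * self.matches / denom if denom else 0.0


def _rolling_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Packed code of the k-mer starting at each offset; -1 where it holds N."""
    n = enc.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(enc, k)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    codes = windows.astype(np.int64) @ powers
    codes[(windows >= 4).any(axis=1)] = -1
    return codes


def seed_query(
    query: SequenceRecord | str, strand: str, index: TileIndex
) -> List[SeedHit]:
    """Look up every overlapping tile of the strand-oriented query.

    Hits are sorted by (t_id, diag, t_pos).  A query shorter than the tile
    size yields no hits.
    """
    residues = query.residues if isinstance(query, SequenceRecord) else query
    if strand == "-":
        residues = revcomp(residues)
    elif strand != "+":
        raise ValueError("strand must be '+' or '-'")
    enc = encode_residues(residues)
    k = index.tile_size
    codes = _rolling_codes(enc, k)
    if codes.shape[0] == 0:
        return []
    member = index.membership(codes)
    q_positions = np.nonzero(member)[0]
    hits: List[SeedHit] = []
    for q_pos in q_positions:
        tids, offs = index.lookup_code(int(codes[q_pos]))
        qp = int(q_pos)
        for t, o in zip(tids, offs):
            hits.append(SeedHit(qp, int(t), int(o), int(o) - qp))
    hits.sort(key=lambda h: (h.t_id, h.diag, h.t_pos))
    return hits


def clump_hits(
    hits: Sequence[SeedHit], params: AlignParams, strand: str = "+"
) -> List[Clump]:
    """Greedy grouping of sorted hits into diagonal-band clumps.

    A hit joins the current clump iff it shares the target, its diagonal is
    within ``diag_slack`` of the clump's running median diagonal, and its
    target distance to the clump span is at most ``clump_gap_max``.  Clumps
    with fewer than ``min_seeds`` hits are discarded.  Output is sorted by
    (t_id, t_min).
    """
    k = params.tile_size
    clumps: List[Clump] = []
    cur: List[SeedHit] = []
    diags: List[int] = []

    def flush() -> None:
        if len(cur) >= params.min_seeds:
            clumps.append(
                Clump(
                    t_id=cur[0].t_id,
                    strand=strand,
                    hits=list(cur),
                    diag_lo=min(diags),
                    diag_hi=max(diags),
                    t_min=min(h.t_pos for h in cur),
                    t_max=max(h.t_pos for h in cur) + k,
                )
            )

    t_lo = t_hi = 0
    for h in hits:
        if cur:
            median = diags[len(diags) // 2]
            if h.t_pos > t_hi:
                gap = h.t_pos - t_hi
            elif h.t_pos + k < t_lo:
                gap = t_lo - (h.t_pos + k)
            else:
                gap = 0
            same = (
                h.t_id == cur[0].t_id
                and abs(h.diag - median) <= params.diag_slack
                and gap <= params.clump_gap_max
            )
            if not same:
                flush()
                cur, diags = [], []
        cur.append(h)
        diags.append(h.diag)
        t_lo = min(t_lo, h.t_pos) if len(cur) > 1 else h.t_pos
        t_hi = max(t_hi, h.t_pos + k) if len(cur) > 1 else h.t_pos + k
    if cur:
        flush()
    clumps.sort(key=lambda c: (c.t_id, c.t_min))
    return clumps


def merge_clumps(clumps: Sequence[Clump], params: AlignParams) -> List[Clump]:
    """Join clumps on the same target whose spans are within intron reach.

    Diagonal-band clumping keeps each exon's hits together but separates
    exons of one gene (an intron shifts the diagonal by its full length),
    so spliced stitching operates on these merged clumps.
    """
    merged: List[Clump] = []
    for c in sorted(clumps, key=lambda c: (c.t_id, c.t_min)):
        if (
            merged
            and merged[-1].t_id == c.t_id
            and c.t_min - merged[-1].t_max <= params.max_intron
        ):
            last = merged[-1]
            last.hits.extend(c.hits)
            last.diag_lo = min(last.diag_lo, c.diag_lo)
            last.diag_hi = max(last.diag_hi, c.diag_hi)
            last.t_min = min(last.t_min, c.t_min)
            last.t_max = max(last.t_max, c.t_max)
        else:
            merged.append(
                Clump(c.t_id, c.strand, list(c.hits), c.diag_lo, c.diag_hi, c.t_min, c.t_max)
            )
    return merged


def _col_score(qc: int, tc: int) -> int:
    if tc == 4:
        return 0           # target N column: neither match nor mismatch
    if qc == tc:
        return 1
    return -1


def _extend_hit(
    q_enc: np.ndarray, t_enc: np.ndarray, q_pos: int, t_pos: int, k: int, x_drop: int
) -> Tuple[int, int]:
    """Ungapped x-drop extension of one seed; returns the scanned query
    extent [q_lo, q_hi) on the hit's diagonal.

    The extent is untrimmed and the scan runs to a drop of x_drop plus a
    full tile: crossing a score valley is profitable whenever a seeded
    continuation (worth at least tile_size matches) lies beyond it, and
    the chain DP — not the extension — decides where alignments end, so
    the extension errs on the side of exposing more cells.
    """
    x_drop = x_drop + k
    n, m = q_enc.shape[0], t_enc.shape[0]
    d = t_pos - q_pos
    # right
    cur = best = 0
    i = q_pos + k
    hi = i
    while i < n and i + d < m:
        cur += _col_score(int(q_enc[i]), int(t_enc[i + d]))
        i += 1
        hi = i
        if cur > best:
            best = cur
        elif cur < best - x_drop:
            break
    # left
    cur = best = 0
    i = q_pos - 1
    lo = q_pos
    while i >= 0 and i + d >= 0:
        cur += _col_score(int(q_enc[i]), int(t_enc[i + d]))
        lo = i
        i -= 1
        if cur > best:
            best = cur
        elif cur < best - x_drop:
            break
    return lo, hi


def _segments_for_clump(
    q_enc: np.ndarray, t_enc: np.ndarray, clump: Clump, params: AlignParams
) -> Dict[int, List[Tuple[int, int]]]:
    """Extend every seed hit (skipping hits already inside an extent) and
    merge overlapping extents per diagonal."""
    k = params.tile_size
    by_diag: Dict[int, List[Tuple[int, int]]] = {}
    hits = sorted(clump.hits, key=lambda h: (h.diag, h.q_pos))
    last_diag: Optional[int] = None
    cov_lo = cov_hi = -1
    for h in hits:
        if h.diag == last_diag and h.q_pos >= cov_lo and h.q_pos + k <= cov_hi:
            continue
        lo, hi = _extend_hit(q_enc, t_enc, h.q_pos, h.t_pos, k, params.x_drop)
        by_diag.setdefault(h.diag, []).append((lo, hi))
        last_diag, cov_lo, cov_hi = h.diag, lo, hi
    # Same-diagonal extents separated by a short valley are joined so the
    # chain DP can weigh aligning straight through it against a gapped
    # junction; x-drop alone would hide those columns from the DP.
    merged: Dict[int, List[Tuple[int, int]]] = {}
    for d, ivals in by_diag.items():
        ivals.sort()
        out = [list(ivals[0])]
        for lo, hi in ivals[1:]:
            if lo <= out[-1][1] + _BRIDGE:
                out[-1][1] = max(out[-1][1], hi)
            else:
                out.append([lo, hi])
        merged[d] = [(lo, hi) for lo, hi in out]
    return merged


class _Row:
    """Finished DP row: sorted target coords, B1 values, prefix maxima."""

    __slots__ = ("ts", "idxs", "b1", "prefmax", "prefarg")

    def __init__(self, ts: List[int], idxs: List[int], b1: List[float]):
        self.ts = ts
        self.idxs = idxs
        self.b1 = b1
        pm: List[float] = []
        pa: List[int] = []
        best = NEG_INF
        arg = -1
        for i, v in enumerate(b1):
            if v > best:
                best, arg = v, i
            pm.append(best)
            pa.append(arg)
        self.prefmax = pm
        self.prefarg = pa

    def cell(self, t: int) -> int:
        """Cell index at target coord t, or -1."""
        i = bisect_left(self.ts, t)
        if i < len(self.ts) and self.ts[i] == t:
            return i
        return -1

    def range_max(self, t_lo: int, t_hi: int) -> Tuple[float, int]:
        """(max B1, cell index) over cells with t in [t_lo, t_hi]; first on tie."""
        hi = bisect_right(self.ts, t_hi) - 1
        if hi < 0:
            return NEG_INF, -1
        if not self.ts or self.ts[0] >= t_lo:
            return self.prefmax[hi], self.prefarg[hi]
        lo = bisect_left(self.ts, t_lo)
        if lo > hi:
            return NEG_INF, -1
        best, arg = NEG_INF, -1
        for i in range(lo, hi + 1):
            if self.b1[i] > best:
                best, arg = self.b1[i], i
        return best, arg


# traceback move codes
_FRESH, _B0_DIAG, _B0_JUNC = 0, 1, 2
_B1_DIAG, _B1_SEED_B0, _B1_SEED_FRESH, _B1_SEED_JUNC = 3, 4, 5, 6


def _chain_dp(
    q_enc: np.ndarray,
    t_enc: np.ndarray,
    segments: Dict[int, List[Tuple[int, int]]],
    index: TileIndex,
    params: AlignParams,
) -> Optional[Tuple[float, List[Tuple[int, int]]]]:
    """Exact chain DP over the sparse cell set defined by the segments.

    State B0: best chain ending at an aligned column whose current block
    does not yet contain an indexed exact tile; B1: it does.  Junctions
    (between blocks) leave only seeded blocks, cost one point per gapped
    side, with target gaps either at most ``max_gap`` or in the intron
    range.  Returns (best score, aligned columns) or None if no seeded
    chain exists.
    """
    k = params.tile_size
    max_gap = params.max_gap
    # ---- build cells grouped by query row
    rows_cells: Dict[int, List[int]] = {}
    for d, ivals in segments.items():
        for lo, hi in ivals:
            lo = max(lo, -d if d < 0 else 0)
            for q in range(lo, hi):
                rows_cells.setdefault(q, []).append(q + d)
    if not rows_cells:
        return None
    q_rows = sorted(rows_cells)
    for q in q_rows:
        rows_cells[q] = sorted(set(rows_cells[q]))

    qcodes = _rolling_codes(q_enc, k)          # code of kmer starting at offset
    n_q = q_enc.shape[0]
    # qk_end_ok[i]: kmer ENDING at query offset i is N-free and in the index
    qk_end_ok = np.zeros(n_q, dtype=bool)
    if qcodes.shape[0]:
        qk_end_ok[k - 1 :] = index.membership(qcodes)

    cells_q: List[int] = []
    cells_t: List[int] = []
    b0: List[float] = []
    b1: List[float] = []
    b0_move: List[int] = []
    b0_pred: List[int] = []
    b1_move: List[int] = []
    b1_pred: List[int] = []
    done_rows: Dict[int, _Row] = {}
    cell_at: Dict[Tuple[int, int], int] = {}

    def junction(q: int, t: int) -> Tuple[float, int, int]:
        """Best way to start a new block at column (q, t): (value, move, pred).

        move is _FRESH or _B0_JUNC (junction from a seeded block); the
        caller reinterprets the move code for its own layer.
        """
        best_v, best_m, best_p = 0.0, _FRESH, -1
        for qg in range(0, max_gap + 1):
            qq = q - 1 - qg
            if qq < 0:
                break
            row = done_rows.get(qq)
            if row is None:
                continue
            q_cost = 1 if qg > 0 else 0
            for tg in range(0, max_gap + 1):
                if qg == 0 and tg == 0:
                    continue
                tp = t - 1 - tg
                if tp < 0:
                    continue
                ci = row.cell(tp)
                if ci >= 0:
                    v = row.b1[ci] - (q_cost + (1 if tg > 0 else 0))
                    if v > best_v:
                        best_v, best_m, best_p = v, _B0_JUNC, row.idxs[ci]
            t_hi = t - 1 - params.min_intron
            if t_hi >= 0:
                v, ci = row.range_max(t - 1 - params.max_intron, t_hi)
                if ci >= 0:
                    v -= 1 + q_cost
                    if v > best_v:
                        best_v, best_m, best_p = v, _B0_JUNC, row.idxs[ci]
        return best_v, best_m, best_p

    best_val, best_idx = NEG_INF, -1
    for q in q_rows:
        row_ts: List[int] = []
        row_idx: List[int] = []
        row_b1: List[float] = []
        qc = int(q_enc[q])
        for t in rows_cells[q]:
            tc = int(t_enc[t])
            s = _col_score(qc, tc)
            idx = len(cells_q)
            cells_q.append(q)
            cells_t.append(t)
            cell_at[(q, t)] = idx

            jv, jm, jp = junction(q, t)
            prev = cell_at.get((q - 1, t - 1), -1)
            if prev >= 0 and b0[prev] >= jv:
                v0, m0, p0 = s + b0[prev], _B0_DIAG, prev
            else:
                v0, m0, p0 = s + jv, jm, jp
            b0.append(v0)
            b0_move.append(m0)
            b0_pred.append(p0)

            if prev >= 0 and b1[prev] > NEG_INF:
                v1, m1, p1 = s + b1[prev], _B1_DIAG, prev
            else:
                v1, m1, p1 = NEG_INF, _B1_DIAG, -1
            if (
                q >= k - 1
                and t >= k - 1
                and qk_end_ok[q]
                and np.array_equal(q_enc[q - k + 1 : q + 1], t_enc[t - k + 1 : t + 1])
            ):
                base = cell_at.get((q - k, t - k), -1)
                sv, sm, sp = NEG_INF, _B1_SEED_FRESH, -1
                if base >= 0 and b0[base] > NEG_INF:
                    sv, sm, sp = b0[base], _B1_SEED_B0, base
                jv2, jm2, jp2 = junction(q - k + 1, t - k + 1)
                if jv2 > sv:
                    sv = jv2
                    sm = _B1_SEED_FRESH if jm2 == _FRESH else _B1_SEED_JUNC
                    sp = jp2
                if k + sv > v1:
                    v1, m1, p1 = k + sv, sm, sp
            b1.append(v1)
            b1_move.append(m1)
            b1_pred.append(p1)

            row_ts.append(t)
            row_idx.append(idx)
            row_b1.append(v1)
            if v1 > best_val:
                best_val, best_idx = v1, idx
        done_rows[q] = _Row(row_ts, row_idx, row_b1)

    if best_idx < 0 or best_val <= NEG_INF:
        return None

    # ---- traceback
    columns: List[Tuple[int, int]] = []
    idx, layer = best_idx, 1
    while idx >= 0:
        q, t = cells_q[idx], cells_t[idx]
        if layer == 1:
            move = b1_move[idx]
            if move == _B1_DIAG:
                columns.append((q, t))
                idx = b1_pred[idx]
                if idx < 0:
                    break
            elif move in (_B1_SEED_B0, _B1_SEED_FRESH, _B1_SEED_JUNC):
                for off in range(k):
                    columns.append((q - off, t - off))
                pred = b1_pred[idx]
                if move == _B1_SEED_B0:
                    idx, layer = pred, 0
                elif move == _B1_SEED_JUNC:
                    idx, layer = pred, 1
                else:
                    break
            else:  # pragma: no cover - defensive
                raise AssertionError("corrupt traceback")
        else:
            move = b0_move[idx]
            columns.append((q, t))
            if move == _B0_DIAG:
                idx = b0_pred[idx]
            elif move == _B0_JUNC:
                idx, layer = b0_pred[idx], 1
            else:  # _FRESH
                break
    columns.reverse()
    return best_val, columns


def _columns_to_alignment(
    columns: List[Tuple[int, int]],
    q_enc: np.ndarray,
    t_enc: np.ndarray,
    q_name: str,
    t_name: str,
    t_id: int,
    strand: str,
    params: AlignParams,
) -> Alignment:
    blocks: List[Tuple[int, int, int]] = []
    bq, bt, size = columns[0][0], columns[0][1], 1
    for q, t in columns[1:]:
        if q == bq + size and t == bt + size:
            size += 1
        else:
            blocks.append((bq, bt, size))
            bq, bt, size = q, t, 1
    blocks.append((bq, bt, size))

    matches = mis = n_count = 0
    for q, t in columns:
        tc = int(t_enc[t])
        if tc == 4:
            n_count += 1
        elif int(q_enc[q]) == tc:
            matches += 1
        else:
            mis += 1
    q_num = q_base = t_num = t_base = introns = 0
    for (pq, pt, ps), (nq, nt, _) in zip(blocks, blocks[1:]):
        qgap = nq - (pq + ps)
        tgap = nt - (pt + ps)
        if qgap > 0:
            q_num += 1
            q_base += qgap
        if tgap > 0:
            if tgap >= params.min_intron:
                introns += 1
            else:
                t_num += 1
                t_base += tgap
    score = matches - mis - q_num - t_num - introns
    return Alignment(
        q_name=q_name,
        t_name=t_name,
        t_id=t_id,
        strand=strand,
        blocks=blocks,
        matches=matches,
        mis_matches=mis,
        n_count=n_count,
        q_num_insert=q_num,
        q_base_insert=q_base,
        t_num_insert=t_num,
        t_base_insert=t_base,
        n_introns=introns,
        score=score,
    )


def extend_clump(
    query_residues: str,
    genome: Genome,
    index: TileIndex,
    clump: Clump,
    params: AlignParams,
    q_name: str = "query",
) -> Optional[Alignment]:
    """Extend and stitch one clump into its best-scoring alignment.

    ``query_residues`` must already be strand-oriented (reverse complement
    for '-' clumps).  Returns None when the best chain fails the score or
    identity thresholds, or when no seeded chain exists.
    """
    q_enc = encode_residues(query_residues)
    t_enc = genome.encoded[clump.t_id]
    segments = _segments_for_clump(q_enc, t_enc, clump, params)
    result = _chain_dp(q_enc, t_enc, segments, index, params)
    if result is None:
        return None
    score, columns = result
    aln = _columns_to_alignment(
        columns, q_enc, t_enc, q_name, genome.names[clump.t_id], clump.t_id,
        clump.strand, params,
    )
    assert aln.score == int(round(score)), "chain DP score disagrees with counts"
    if aln.score < params.min_score or aln.identity < params.min_identity:
        return None
    return aln


def _alignment_to_psl(aln: Alignment, q_size: int, t_size: int) -> PslRecord:
    block_sizes = [s for (_, _, s) in aln.blocks]
    q_starts = [q for (q, _, _) in aln.blocks]
    t_starts = [t for (_, t, _) in aln.blocks]
    q_lo = aln.blocks[0][0]
    q_hi = aln.blocks[-1][0] + aln.blocks[-1][2]
    if aln.strand == "+":
        q_start, q_end = q_lo, q_hi
    else:
        q_start, q_end = q_size - q_hi, q_size - q_lo
    return PslRecord(
        matches=aln.matches,
        misMatches=aln.mis_matches,
        repMatches=0,
        nCount=aln.n_count,
        qNumInsert=aln.q_num_insert,
        qBaseInsert=aln.q_base_insert,
        tNumInsert=aln.t_num_insert,
        tBaseInsert=aln.t_base_insert,
        strand=aln.strand,
        qName=aln.q_name,
        qSize=q_size,
        qStart=q_start,
        qEnd=q_end,
        tName=aln.t_name,
        tSize=t_size,
        tStart=aln.blocks[0][1],
        tEnd=aln.blocks[-1][1] + aln.blocks[-1][2],
        blockCount=len(aln.blocks),
        blockSizes=block_sizes,
        qStarts=q_starts,
        tStarts=t_starts,
    )


def align_query(
    query: SequenceRecord, genome: Genome, index: TileIndex, params: AlignParams
) -> List[PslRecord]:
    """Map one query on both strands; return all surviving alignments as
    PSL records sorted by (score descending, tName, tStart, qStart)."""
    if len(query.residues) < params.tile_size:
        return []
    results: List[Tuple[int, str, int, int, Alignment]] = []
    for strand in ("+", "-"):
        oriented = query.residues if strand == "+" else revcomp(query.residues)
        hits = seed_query(oriented, "+", index)
        clumps = clump_hits(hits, params, strand=strand)
        for clump in merge_clumps(clumps, params):
            aln = extend_clump(oriented, genome, index, clump, params, q_name=query.name)
            if aln is not None:
                results.append(
                    (aln.score, aln.t_name, aln.blocks[0][1], aln.blocks[0][0], aln)
                )
    results.sort(key=lambda r: (-r[0], r[1], r[2], r[3], r[4].strand))
    q_size = len(query.residues)
    return [
        _alignment_to_psl(aln, q_size, genome.sizes[aln.t_id])
        for (_, _, _, _, aln) in results
    ]


def psl_score(rec: PslRecord, min_intron: int = 30) -> int:
    """Chain score of a PSL record under this aligner's cost model:
    matches - misMatches - gap openings, introns charged one point each."""
    introns = 0
    for i in range(rec.blockCount - 1):
        tgap = rec.tStarts[i + 1] - (rec.tStarts[i] + rec.blockSizes[i])
        if tgap >= min_intron:
            introns += 1
    return rec.matches - rec.misMatches - rec.qNumInsert - rec.tNumInsert - introns
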