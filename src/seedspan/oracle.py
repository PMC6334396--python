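"""Exhaustive intron-aware alignment DP, for validating the aligner.

This is a dense, quadratic reference implementation of the aligner's cost
model: local alignment scoring match +1, mismatch -1 (target-N columns 0),
one point per gap opening with gap bases free — query gaps at most
``max_gap`` bases, target gaps either at most ``max_gap`` bases or in the
intron range [min_intron, max_intron] (an intron costs one gap opening) —
restricted to block chains in which every block contains at least one
exact tile whose string is present in the genome index.

It explores every cell of the query x target matrix, independently of the
seed/clump/extend heuristics, and is only usable at small scale (queries
of a few hundred bases, targets of a few kilobases).  The production
aligner is expected to reach the same optimum whenever its seeds cover the
optimal chain; tests and the acceptance script assert exactly that.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .aligner_core import AlignParams, revcomp
from .genome_index import TileIndex, encode_residues

__all__ = ["oracle_best_score", "oracle_best_score_both_strands"]

NEG_INF = float("-inf")


def _rolling_end_ok(q_enc: np.ndarray, k: int, index: TileIndex) -> np.ndarray:
    """qk[i]: the k-mer ending at query offset i is N-free and indexed."""
    n = q_enc.shape[0]
    ok = np.zeros(n, dtype=bool)
    if n < k:
        return ok
    windows = np.lib.stride_tricks.sliding_window_view(q_enc, k)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    codes = windows.astype(np.int64) @ powers
    codes[(windows >= 4).any(axis=1)] = -1
    ok[k - 1 :] = index.membership(codes)
    return ok


def _shift(arr: np.ndarray, d: int) -> np.ndarray:
    out = np.full(arr.shape[0], NEG_INF)
    if d < arr.shape[0]:
        out[d:] = arr[: arr.shape[0] - d]
    return out


def oracle_best_score(
    query: str, target: str, index: TileIndex, params: AlignParams
) -> Optional[int]:
    """Optimal seeded chain score of ``query`` (as given, one strand)
    against ``target``; None when no seeded chain exists.

    Requires ``params.max_intron >= len(target)`` (the full-prefix maximum
    shortcut assumes the intron upper bound never truncates the search;
    with kilobase test targets and the default 750 kb bound this always
    holds).
    """
    if params.max_intron < len(target):
        raise ValueError("oracle requires max_intron >= target length")
    q_enc = encode_residues(query)
    t_enc = encode_residues(target)
    n, m = q_enc.shape[0], t_enc.shape[0]
    k = params.tile_size
    if n < k or m < k:
        return None
    qk_ok = _rolling_end_ok(q_enc, k, index)
    max_gap = params.max_gap

    b0_rows: List[np.ndarray] = []
    b1_rows: List[np.ndarray] = []
    pref_rows: List[np.ndarray] = []
    j_rows: List[np.ndarray] = []
    run_prev = np.zeros(m, dtype=np.int32)
    best = NEG_INF

    t_is_n = t_enc == 4
    for i in range(n):
        qc = q_enc[i]
        eq = (t_enc == qc) & ~t_is_n & (qc < 4)
        s = np.where(t_is_n, 0.0, np.where(eq, 1.0, -1.0))

        run = np.zeros(m, dtype=np.int32)
        run[0] = 1 if eq[0] else 0
        run[1:] = np.where(eq[1:], run_prev[:-1] + 1, 0)

        j_row = np.zeros(m)
        for qg in range(0, max_gap + 1):
            ip = i - 1 - qg
            if ip < 0:
                break
            b1p = b1_rows[ip]
            q_cost = 1.0 if qg > 0 else 0.0
            for tg in range(0, max_gap + 1):
                if qg == 0 and tg == 0:
                    continue
                cand = _shift(b1p, tg + 1) - (q_cost + (1.0 if tg > 0 else 0.0))
                np.maximum(j_row, cand, out=j_row)
            cand = _shift(pref_rows[ip], params.min_intron + 1) - (1.0 + q_cost)
            np.maximum(j_row, cand, out=j_row)

        if i == 0:
            b0 = s + j_row
            b1 = np.full(m, NEG_INF)
        else:
            b0 = s + np.maximum(_shift(b0_rows[i - 1], 1), j_row)
            b1 = s + _shift(b1_rows[i - 1], 1)

        se = (run >= k) & qk_ok[i]
        if se.any():
            base = _shift(j_rows[i - k + 1], k - 1) if i - k + 1 >= 0 else None
            if i - k >= 0:
                base = np.maximum(base, _shift(b0_rows[i - k], k))
            cand = k + base
            b1 = np.where(se, np.maximum(b1, cand), b1)

        pref = np.maximum.accumulate(b1)
        b0_rows.append(b0)
        b1_rows.append(b1)
        pref_rows.append(pref)
        j_rows.append(j_row)
        run_prev = run
        row_best = b1.max()
        if row_best > best:
            best = row_best

    if best == NEG_INF:
        return None
    return int(round(best))


def oracle_best_score_both_strands(
    query: str, target: str, index: TileIndex, params: AlignParams
) -> Optional[int]:
    """Best seeded chain score over the forward and reverse-complement
    orientations of the query."""
    fwd = oracle_best_score(query, target, index, params)
    rev = oracle_best_score(revcomp(query), target, index, params)
    vals = [v for v in (fwd, rev) if v is not None]
    return max(vals) if vals else None
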