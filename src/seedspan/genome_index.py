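"""Genome container and the shared k-mer tile index.

The index maps every fixed-length, N-free tile sampled at a fixed step
along each target to its (target, offset) positions.  It is built once,
before workers start, and is read-only afterwards: all parallelism in this
package rests on every worker querying the same index instance (the
one-copy memory contract).

Storage is CSR-style: three flat numpy arrays (sorted unique tile codes,
row offsets, positions).  Flat buffers matter here — forked worker
processes share them copy-on-write without touching object headers, so
resident memory stays essentially independent of worker count.  Tiles
occurring more often than ``overused_cutoff`` are dropped entirely (not
sampled), keeping lookups deterministic, which the byte-identity guarantee
across worker counts requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from .seq_io import SequenceRecord

__all__ = ["Genome", "TileIndex", "build_index", "encode_residues"]

# A,C,G,T -> 0..3; N (and only N, after seq_io normalization) -> 4.
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
_DEC = np.array(list("ACGTN"))


def encode_residues(residues: str) -> np.ndarray:
    """Encode an A/C/G/T/N string as uint8 codes 0..4 (N = 4)."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return _ENC[raw]


class Genome:
    """Ordered collection of target sequences with cached encodings.

    Target names must be unique.  Encoded arrays are computed eagerly so
    that forked workers inherit them rather than re-encoding.
    """

    def __init__(self, targets: Sequence[SequenceRecord]):
        if not targets:
            raise ValueError("genome must contain at least one target sequence")
        names = [t.name for t in targets]
        if len(set(names)) != len(names):
            raise ValueError("target names must be unique")
        self.targets: List[SequenceRecord] = list(targets)
        self.names: List[str] = names
        self.sizes: List[int] = [len(t.residues) for t in targets]
        self.name_to_id: Dict[str, int] = {n: i for i, n in enumerate(names)}
        self.encoded: List[np.ndarray] = [encode_residues(t.residues) for t in targets]

    def __len__(self) -> int:
        return len(self.targets)


def _tile_codes(enc: np.ndarray, k: int, step: int) -> Tuple[np.ndarray, np.ndarray]:
    """Return (offsets, codes) of N-free tiles at offsets 0, step, 2*step, ...

    Code of a tile is its base-4 big-endian packing; tiles containing N are
    excluded.
    """
    n = enc.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    offsets = np.arange(0, n - k + 1, step, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(enc, k)[::step]
    valid = (windows < 4).all(axis=1)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    codes = windows[valid].astype(np.int64) @ powers
    return offsets[valid], codes


def encode_tile(tile: str) -> int:
    """Base-4 packing of an N-free tile string; -1 if the tile contains N."""
    enc = encode_residues(tile.upper())
    if (enc >= 4).any():
        return -1
    k = enc.shape[0]
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    return int(enc.astype(np.int64) @ powers)


def decode_tile(code: int, k: int) -> str:
    digits = []
    for _ in range(k):
        digits.append(code % 4)
        code //= 4
    return "".join(_DEC[d] for d in reversed(digits))


@dataclass
class TileIndex:
    """Read-only map from tile code to sorted (targetId, offset) positions."""

    tile_size: int
    step_size: int
    overused_cutoff: int
    codes: np.ndarray        # sorted unique tile codes kept in the table
    starts: np.ndarray       # CSR row offsets into tids/offs, len == len(codes)+1
    tids: np.ndarray         # target ids, grouped by code, sorted by (tid, off)
    offs: np.ndarray         # target offsets, same order as tids
    overused_codes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def n_tiles(self) -> int:
        return int(self.codes.shape[0])

    @property
    def overused(self) -> Set[str]:
        """Tile strings dropped for exceeding the overuse cutoff."""
        return {decode_tile(int(c), self.tile_size) for c in self.overused_codes}

    def lookup_code(self, code: int) -> Tuple[np.ndarray, np.ndarray]:
        """Positions for one packed tile code: (tids, offs), possibly empty."""
        i = np.searchsorted(self.codes, code)
        if i < self.codes.shape[0] and self.codes[i] == code:
            lo, hi = self.starts[i], self.starts[i + 1]
            return self.tids[lo:hi], self.offs[lo:hi]
        empty = np.empty(0, dtype=self.tids.dtype)
        return empty, empty

    def lookup(self, tile: str) -> List[Tuple[int, int]]:
        """Stored positions of a tile string, sorted by (targetId, offset).

        Tiles containing N, overused tiles and absent tiles return [].
        """
        if len(tile) != self.tile_size:
            raise ValueError(
                f"tile length {len(tile)} != index tile size {self.tile_size}"
            )
        code = encode_tile(tile)
        if code < 0:
            return []
        tids, offs = self.lookup_code(code)
        return [(int(t), int(o)) for t, o in zip(tids, offs)]

    def has_tile(self, code: int) -> bool:
        i = np.searchsorted(self.codes, code)
        return bool(i < self.codes.shape[0] and self.codes[i] == code)

    def membership(self, codes: np.ndarray) -> np.ndarray:
        """Vectorized has_tile over an int64 array (negative codes -> False)."""
        safe = np.clip(codes, 0, None)
        i = np.searchsorted(self.codes, safe)
        i = np.clip(i, 0, max(self.codes.shape[0] - 1, 0))
        if self.codes.shape[0] == 0:
            return np.zeros(codes.shape, dtype=bool)
        return (self.codes[i] == codes) & (codes >= 0)


def build_index(
    genome: Genome, tile_size: int = 11, step_size: int = 11, overused_cutoff: int = 1024
) -> TileIndex:
    """Single pass over each target: collect N-free tiles at step offsets,
    drop tiles whose indexed occurrence count exceeds the cutoff, and pack
    the rest into CSR arrays sorted by (code, targetId, offset).

    The result is a pure function of (genome, tile_size, step_size,
    overused_cutoff).  Occurrences are counted after N-exclusion, over the
    step-aligned positions that would be indexed.
    """
    if not (4 <= tile_size <= 18):
        raise ValueError("tile_size must be in [4, 18]")
    if not (1 <= step_size <= tile_size):
        raise ValueError("step_size must be in [1, tile_size]")
    if overused_cutoff < 1:
        raise ValueError("overused_cutoff must be >= 1")

    all_codes, all_tids, all_offs = [], [], []
    for tid, enc in enumerate(genome.encoded):
        offs, codes = _tile_codes(enc, tile_size, step_size)
        all_codes.append(codes)
        all_offs.append(offs)
        all_tids.append(np.full(codes.shape[0], tid, dtype=np.int32))
    codes = np.concatenate(all_codes) if all_codes else np.empty(0, dtype=np.int64)
    tids = np.concatenate(all_tids) if all_tids else np.empty(0, dtype=np.int32)
    offs = np.concatenate(all_offs) if all_offs else np.empty(0, dtype=np.int64)

    order = np.lexsort((offs, tids, codes))
    codes, tids, offs = codes[order], tids[order], offs[order]

    uniq, first, counts = np.unique(codes, return_index=True, return_counts=True)
    keep = counts <= overused_cutoff
    overused_codes = uniq[~keep]

    if overused_codes.shape[0]:
        keep_rows = np.ones(codes.shape[0], dtype=bool)
        for u, f, c in zip(uniq[~keep], first[~keep], counts[~keep]):
            keep_rows[f : f + c] = False
        codes, tids, offs = codes[keep_rows], tids[keep_rows], offs[keep_rows]
        uniq, counts = uniq[keep], counts[keep]

    starts = np.zeros(uniq.shape[0] + 1, dtype=np.int64)
    np.cumsum(counts, out=starts[1:])
    return TileIndex(
        tile_size=tile_size,
        step_size=step_size,
        overused_cutoff=overused_cutoff,
        codes=uniq,
        starts=starts,
        tids=tids,
        offs=offs.astype(np.int64),
        overused_codes=overused_codes,
    )
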