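"""Data-level parallel execution with deterministic, order-preserving merge.

The query file is *virtually* divided into as many equal-count parts as
there are workers: parts are (startOrdinal, length) ranges over one shared
parsed query list, never physical file splits.  Every worker receives a
read-only reference to the same genome and tile index — built exactly once
before workers start — processes its part in ordinal order, and appends to
its own temporary file.  When all workers finish, the temporary files are
concatenated in part order, which makes the final output byte-identical to
a single-worker run no matter how many workers were used.

Two worker mechanisms satisfy the contract:

``process`` (default)
    Forked OS processes.  The genome and index live in flat numpy buffers,
    so forked children share them copy-on-write; resident memory grows by
    per-interpreter working state only, never by another copy of the
    genome or index.  This is the mechanism that yields real speedup on
    multicore machines.

``thread``
    In-process threads, the closest analog of the pthread design this
    package emulates: one address space, one genome, one index, shared
    exactly.  Thread workers interleave under the interpreter lock, so
    they demonstrate the memory contract rather than wall-clock speedup.
"""

from __future__ import annotations

import os
import shutil
import tempfile
import threading
import time
from dataclasses import dataclass, field
from multiprocessing import get_context
from typing import IO, List, Optional, Sequence, Tuple, Union

from .aligner_core import AlignParams, align_query
from .genome_index import Genome, TileIndex, build_index
from .seq_io import PSL_HEADER, SequenceRecord, read_fasta

__all__ = [
    "ChunkPlan",
    "WorkerOutput",
    "RunResult",
    "plan_chunks",
    "run_parallel",
    "merge_outputs",
    "load_queries",
]

_MP = get_context("fork")


@dataclass(frozen=True)
class ChunkPlan:
    """Equal-count virtual partition of the query stream.

    When n_queries = q * n_parts + r, the first r parts hold q+1 queries
    and the rest hold q, so any two part lengths differ by at most one.
    """

    n_queries: int
    n_parts: int
    parts: Tuple[Tuple[int, int], ...]  # (start_ordinal, length)


def plan_chunks(n_queries: int, requested_workers: int) -> ChunkPlan:
    """Deterministic equal-count split; remainder queries go to the
    leading parts.  The part count is capped at the query count (an idle
    worker gets no part), except that an empty input yields one empty
    part."""
    if requested_workers < 1:
        raise ValueError("requested_workers must be >= 1")
    if n_queries < 0:
        raise ValueError("n_queries must be >= 0")
    n_parts = min(requested_workers, max(n_queries, 1))
    q, r = divmod(n_queries, n_parts)
    parts = []
    start = 0
    for i in range(n_parts):
        length = q + 1 if i < r else q
        parts.append((start, length))
        start += length
    return ChunkPlan(n_queries=n_queries, n_parts=n_parts, parts=tuple(parts))


@dataclass
class WorkerOutput:
    """One part's temporary, headerless PSL sink."""

    part_index: int
    path: str


@dataclass
class RunResult:
    n_queries: int
    n_parts: int
    n_records: int
    peak_pss_bytes: Optional[int] = None


def load_queries(
    source: Union[str, os.PathLike, IO, Sequence[SequenceRecord]]
) -> List[SequenceRecord]:
    """Materialize the ordered query list from a FASTA path/stream, or pass
    an already-parsed record list through (ordinals must be 0..n-1)."""
    if isinstance(source, (list, tuple)):
        for i, rec in enumerate(source):
            if rec.ordinal != i:
                raise ValueError("query ordinals must be consecutive from 0")
        return list(source)
    return list(read_fasta(source))


def _worker_job(
    part_index: int,
    start: int,
    length: int,
    queries: Sequence[SequenceRecord],
    genome: Genome,
    index: TileIndex,
    params: AlignParams,
    path: str,
) -> None:
    with open(path, "w", encoding="ascii", newline="") as out:
        for rec in queries[start : start + length]:
            for psl in align_query(rec, genome, index, params):
                out.write(psl.to_line())


def merge_outputs(
    outputs: Sequence[WorkerOutput], header: bool, out: IO
) -> int:
    """Concatenate part sinks in part order into ``out``; emit the PSL
    header at most once, at the front.  Deletes the temporary sinks.
    Returns the number of records written.  A gap in the part indices is
    an error naming the first missing part."""
    by_index = {o.part_index: o for o in outputs}
    for i in range(len(outputs)):
        if i not in by_index:
            raise ValueError(f"missing worker output for part {i}")
    n_records = 0
    if header:
        out.write(PSL_HEADER)
    for i in range(len(outputs)):
        path = by_index[i].path
        with open(path, "r", encoding="ascii", newline="") as src:
            for line in src:
                out.write(line)
                n_records += 1
        os.unlink(path)
    return n_records


def _read_pss(pid: int) -> int:
    try:
        with open(f"/proc/{pid}/smaps_rollup", "r") as fh:
            for line in fh:
                if line.startswith("Pss:"):
                    return int(line.split()[1]) * 1024
    except OSError:
        return 0
    return 0


class _PssMonitor:
    """Samples the summed proportional-set-size of a set of pids.

    PSS divides shared pages among their sharers, so the sum over the
    worker tree measures real memory use: a worker that duplicated the
    genome or index would show up fully, copy-on-write sharing does not.
    """

    def __init__(self, pids: Sequence[int], interval: float = 0.02):
        self.pids = list(pids)
        self.interval = interval
        self.peak = 0
        self._stop = threading.Event()
        self._thread = threading.Thread(target=self._run, daemon=True)

    def _run(self) -> None:
        while not self._stop.is_set():
            total = sum(_read_pss(p) for p in self.pids)
            if total > self.peak:
                self.peak = total
            time.sleep(self.interval)

    def __enter__(self) -> "_PssMonitor":
        self._thread.start()
        return self

    def __exit__(self, *exc) -> None:
        self._stop.set()
        self._thread.join()
        total = sum(_read_pss(p) for p in self.pids)
        if total > self.peak:
            self.peak = total


def run_parallel(
    queries: Union[str, os.PathLike, IO, Sequence[SequenceRecord]],
    genome: Genome,
    params: AlignParams,
    workers: int,
    out_sink: Union[str, os.PathLike, IO],
    header: bool = False,
    scratch_dir: Optional[str] = None,
    mechanism: str = "process",
    index: Optional[TileIndex] = None,
    monitor_memory: bool = False,
    progress=None,
) -> RunResult:
    """Align all queries with ``workers`` parallel workers.

    The tile index is built once (or taken from ``index``) and shared
    read-only by every worker.  Output bytes are identical for any worker
    count.  A worker failure aborts the run with an error naming the part;
    partial temporary outputs are removed.

    ``progress``, when given, is called as ``progress(part_index)`` as each
    part completes (parent side, in completion order).
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    if mechanism not in ("process", "thread"):
        raise ValueError("mechanism must be 'process' or 'thread'")
    query_list = load_queries(queries)
    if index is None:
        index = build_index(
            genome, params.tile_size, params.step_size, params.overused_cutoff
        )
    plan = plan_chunks(len(query_list), workers)

    tmp_dir = tempfile.mkdtemp(prefix="seedspan_", dir=scratch_dir)
    outputs = [
        WorkerOutput(i, os.path.join(tmp_dir, f"part{i}.psl"))
        for i in range(plan.n_parts)
    ]
    peak: Optional[int] = None
    try:
        if plan.n_parts == 1 and not monitor_memory:
            _worker_job(0, *plan.parts[0], query_list, genome, index, params,
                        outputs[0].path)
            if progress is not None:
                progress(0)
        elif mechanism == "thread":
            errors: List[Optional[BaseException]] = [None] * plan.n_parts

            def tjob(i: int) -> None:
                try:
                    _worker_job(i, *plan.parts[i], query_list, genome, index,
                                params, outputs[i].path)
                except BaseException as exc:  # noqa: BLE001 - reported to caller
                    errors[i] = exc

            threads = [
                threading.Thread(target=tjob, args=(i,)) for i in range(plan.n_parts)
            ]
            mon = _PssMonitor([os.getpid()]) if monitor_memory else None
            if mon:
                mon.__enter__()
            try:
                for t in threads:
                    t.start()
                for i, t in enumerate(threads):
                    t.join()
                    if progress is not None:
                        progress(i)
            finally:
                if mon:
                    mon.__exit__()
                    peak = mon.peak
            for i, exc in enumerate(errors):
                if exc is not None:
                    raise RuntimeError(f"worker for part {i} failed: {exc}") from exc
        else:
            procs = [
                _MP.Process(
                    target=_worker_job,
                    args=(i, *plan.parts[i], query_list, genome, index, params,
                          outputs[i].path),
                )
                for i in range(plan.n_parts)
            ]
            for p in procs:
                p.start()
            mon = (
                _PssMonitor([os.getpid()] + [p.pid for p in procs])
                if monitor_memory
                else None
            )
            if mon:
                mon.__enter__()
            try:
                for i, p in enumerate(procs):
                    p.join()
                    if progress is not None:
                        progress(i)
            finally:
                if mon:
                    mon.__exit__()
                    peak = mon.peak
            for i, p in enumerate(procs):
                if p.exitcode != 0:
                    raise RuntimeError(
                        f"worker for part {i} failed with exit code {p.exitcode}"
                    )
        own = isinstance(out_sink, (str, os.PathLike))
        out = open(out_sink, "w", encoding="ascii", newline="") if own else out_sink
        try:
            n_records = merge_outputs(outputs, header, out)
        finally:
            if own:
                out.close()
    except Exception:
        shutil.rmtree(tmp_dir, ignore_errors=True)
        raise
    shutil.rmtree(tmp_dir, ignore_errors=True)
    return RunResult(
        n_queries=len(query_list),
        n_parts=plan.n_parts,
        n_records=n_records,
        peak_pss_bytes=peak,
    )
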