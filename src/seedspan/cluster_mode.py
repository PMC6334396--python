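"""Emulated master/node/thread scatter-gather on one machine.

Queries are split equal-count across nodes first, then each node's slice is
split equal-count across its threads — the same two-level structure a real
deployment would use, where a master hands virtual parts to nodes and
co-located workers merge into one shared-memory multithread group.  Each
emulated node is an OS process running the standard parallel engine on its
slice; the master concatenates node outputs in node order, so output bytes
are invariant over every (nodes x threads) topology, including 1x1.

Only the topology and merge order are contractual.  An MPI launcher could
stand behind the same :class:`NodePlan` without changing a byte of output;
network transport is deliberately out of scope.
"""

from __future__ import annotations

import os
import shutil
import tempfile
from dataclasses import dataclass
from multiprocessing import get_context
from typing import IO, List, Optional, Sequence, Tuple, Union

from .aligner_core import AlignParams
from .genome_index import Genome, TileIndex, build_index
from .parallel_exec import (
    ChunkPlan,
    RunResult,
    load_queries,
    plan_chunks,
    run_parallel,
)
from .seq_io import PSL_HEADER, SequenceRecord

__all__ = ["NodePlan", "plan_nodes", "run_cluster"]

_MP = get_context("fork")


@dataclass(frozen=True)
class NodePlan:
    """Two-level equal-count partition: nodes first, then threads."""

    n_nodes: int
    threads_per_node: int
    node_parts: ChunkPlan
    per_node_plans: Tuple[ChunkPlan, ...]

    def flattened(self) -> List[Tuple[int, int]]:
        """Single-level (start, length) parts, in node then thread order."""
        flat: List[Tuple[int, int]] = []
        for (node_start, node_len), sub in zip(
            self.node_parts.parts, self.per_node_plans
        ):
            if node_len == 0:
                continue
            for start, length in sub.parts:
                if length:
                    flat.append((node_start + start, length))
        return flat


def plan_nodes(n_queries: int, n_nodes: int, threads_per_node: int) -> NodePlan:
    """Split queries equal-count across nodes, then each node slice
    equal-count across its threads (thread count capped at the slice
    size)."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if threads_per_node < 1:
        raise ValueError("threads_per_node must be >= 1")
    node_parts = plan_chunks(n_queries, n_nodes)
    per_node = tuple(
        plan_chunks(length, threads_per_node) for (_, length) in node_parts.parts
    )
    return NodePlan(
        n_nodes=n_nodes,
        threads_per_node=threads_per_node,
        node_parts=node_parts,
        per_node_plans=per_node,
    )


def _node_job(
    node_id: int,
    queries: Sequence[SequenceRecord],
    start: int,
    length: int,
    genome: Genome,
    index: TileIndex,
    params: AlignParams,
    threads: int,
    path: str,
    scratch_dir: Optional[str],
    mechanism: str,
) -> None:
    part = [
        SequenceRecord(r.name, r.description, r.residues, i)
        for i, r in enumerate(queries[start : start + length])
    ]
    run_parallel(
        part,
        genome,
        params,
        workers=max(threads, 1),
        out_sink=path,
        header=False,
        scratch_dir=scratch_dir,
        mechanism=mechanism,
        index=index,
    )


def run_cluster(
    queries: Union[str, os.PathLike, IO, Sequence[SequenceRecord]],
    genome: Genome,
    params: AlignParams,
    n_nodes: int,
    threads_per_node: int,
    out_sink: Union[str, os.PathLike, IO],
    header: bool = False,
    scratch_dir: Optional[str] = None,
    mechanism: str = "process",
    index: Optional[TileIndex] = None,
) -> RunResult:
    """Run the emulated cluster topology; output bytes equal a serial run.

    A node failure aborts the run with an error naming the node; all
    temporary outputs are removed.
    """
    query_list = load_queries(queries)
    if index is None:
        index = build_index(
            genome, params.tile_size, params.step_size, params.overused_cutoff
        )
    plan = plan_nodes(len(query_list), n_nodes, threads_per_node)

    tmp_dir = tempfile.mkdtemp(prefix="seedspan_cluster_", dir=scratch_dir)
    node_paths = [
        os.path.join(tmp_dir, f"node{i}.psl") for i in range(plan.node_parts.n_parts)
    ]
    try:
        procs = []
        for node_id, (start, length) in enumerate(plan.node_parts.parts):
            p = _MP.Process(
                target=_node_job,
                args=(node_id, query_list, start, length, genome, index, params,
                      min(threads_per_node, max(length, 1)), node_paths[node_id],
                      tmp_dir, mechanism),
            )
            p.start()
            procs.append(p)
        for node_id, p in enumerate(procs):
            p.join()
            if p.exitcode != 0:
                raise RuntimeError(
                    f"node {node_id} failed with exit code {p.exitcode}"
                )
        own = isinstance(out_sink, (str, os.PathLike))
        out = open(out_sink, "w", encoding="ascii", newline="") if own else out_sink
        n_records = 0
        try:
            if header:
                out.write(PSL_HEADER)
            for path in node_paths:
                with open(path, "r", encoding="ascii", newline="") as src:
                    for line in src:
                        out.write(line)
                        n_records += 1
        finally:
            if own:
                out.close()
    finally:
        shutil.rmtree(tmp_dir, ignore_errors=True)
    return RunResult(
        n_queries=len(query_list),
        n_parts=len(plan.flattened()),
        n_records=n_records,
    )
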