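"""FASTA input and PSL output.

Readers yield :class:`SequenceRecord` objects in file order, tagged with
their input ordinal — the ordinal is what the parallel partitioner and the
order-preserving merge are built on.  The PSL writer is a pure function of
the record stream and always uses ``\\n`` line endings, so output bytes are
reproducible regardless of platform or worker count.

PSL is the 21-column tab-separated alignment format of the BLAT family:
0-based half-open coordinates, comma-terminated integer-list columns.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, List, Union

__all__ = [
    "SequenceRecord",
    "PslRecord",
    "PslValidationError",
    "FastaError",
    "read_fasta",
    "write_psl",
    "parse_psl",
    "PSL_HEADER",
]

_NON_DNA = re.compile(r"[^ACGTN]")

#: Conventional 5-line PSL header (emitted once, at the top, when enabled).
PSL_HEADER = (
    "psLayout version 3\n"
    "\n"
    "match\tmis- \trep. \tN's\tQ gap\tQ gap\tT gap\tT gap\tstrand\tQ        "
    "\tQ   \tQ    \tQ  \tT        \tT   \tT    \tT  \tblock\tblockSizes "
    "\tqStarts\t tStarts\n"
    "     \tmatch\tmatch\t   \tcount\tbases\tcount\tbases\t      \tname     "
    "\tsize\tstart\tend\tname     \tsize\tstart\tend\tcount\n"
    + "-" * 159
    + "\n"
)


class FastaError(ValueError):
    """Malformed FASTA input."""


class PslValidationError(ValueError):
    """A PslRecord violates a structural invariant."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named DNA sequence with its 0-based position in the input file.

    ``residues`` are uppercased and restricted to {A,C,G,T,N}; any other
    input character has been mapped to N (IUPAC ambiguity codes lose
    information, but the aligner treats N as never-matching, so the loss is
    bounded).  ``name`` is the first whitespace-delimited token of the
    header; ``description`` is the remainder.
    """

    name: str
    description: str
    residues: str
    ordinal: int

    def __len__(self) -> int:
        return len(self.residues)


def _normalize_residues(raw: str) -> str:
    return _NON_DNA.sub("N", raw.upper())


def read_fasta(source: Union[str, os.PathLike, IO]) -> Iterator[SequenceRecord]:
    """Yield :class:`SequenceRecord` from a FASTA path or text stream.

    Records are yielded in file order with ordinals 0..n-1.  Multi-line
    sequences are concatenated; lowercase is uppercased; characters outside
    {A,C,G,T,N} become N.  An empty file yields nothing.  A header with an
    empty name, a record with an empty sequence, or sequence data before
    the first header raises :class:`FastaError` naming the offending line
    or record.
    """
    own = False
    if isinstance(source, (str, os.PathLike)):
        handle: IO = open(source, "r", encoding="ascii")
        own = True
    elif isinstance(source, (bytes, bytearray)):
        raise TypeError("read_fasta expects a path or text stream")
    else:
        handle = source
    try:
        name = None
        description = ""
        chunks: List[str] = []
        ordinal = 0
        header_line = 0
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    yield _finish_record(name, description, chunks, ordinal, header_line)
                    ordinal += 1
                header = line[1:].strip()
                if not header:
                    raise FastaError(f"empty sequence name in header at line {lineno}")
                parts = header.split(None, 1)
                name = parts[0]
                description = parts[1] if len(parts) > 1 else ""
                header_line = lineno
                chunks = []
            else:
                if name is None:
                    raise FastaError(
                        f"sequence data before first '>' header at line {lineno}"
                    )
                chunks.append(line)
        if name is not None:
            yield _finish_record(name, description, chunks, ordinal, header_line)
    finally:
        if own:
            handle.close()


def _finish_record(
    name: str, description: str, chunks: List[str], ordinal: int, header_line: int
) -> SequenceRecord:
    residues = _normalize_residues("".join(chunks))
    if not residues:
        raise FastaError(
            f"record '{name}' (header at line {header_line}) has an empty sequence"
        )
    return SequenceRecord(name=name, description=description, residues=residues, ordinal=ordinal)


@dataclass
class PslRecord:
    """One alignment in PSL layout (21 fields).

    Coordinates are 0-based half-open.  For '-' strand records ``qStarts``
    are in reverse-complement query coordinates while ``qStart``/``qEnd``
    are on the forward query, per PSL convention.  ``repMatches`` is always
    0 here: no repeat-masking logic exists in this aligner, and downstream
    consumers should not read repeat information into that column.
    """

    matches: int
    misMatches: int
    repMatches: int
    nCount: int
    qNumInsert: int
    qBaseInsert: int
    tNumInsert: int
    tBaseInsert: int
    strand: str
    qName: str
    qSize: int
    qStart: int
    qEnd: int
    tName: str
    tSize: int
    tStart: int
    tEnd: int
    blockCount: int
    blockSizes: List[int] = field(default_factory=list)
    qStarts: List[int] = field(default_factory=list)
    tStarts: List[int] = field(default_factory=list)

    def validate(self) -> None:
        """Raise :class:`PslValidationError` on the first violated invariant."""
        r = self

        def bad(msg: str) -> None:
            raise PslValidationError(f"PSL record {r.qName} -> {r.tName}: {msg}")

        if r.strand not in ("+", "-"):
            bad(f"strand must be '+' or '-', got {r.strand!r}")
        if not (r.blockCount == len(r.blockSizes) == len(r.qStarts) == len(r.tStarts)):
            bad("blockCount disagrees with list lengths")
        if r.blockCount < 1:
            bad("blockCount must be >= 1")
        if r.matches + r.misMatches + r.repMatches + r.nCount != sum(r.blockSizes):
            bad("matches + misMatches + repMatches + nCount != sum(blockSizes)")
        if any(s < 1 for s in r.blockSizes):
            bad("blockSizes must be positive")
        for i in range(r.blockCount - 1):
            if r.tStarts[i] + r.blockSizes[i] > r.tStarts[i + 1]:
                bad("target blocks overlap or are out of order")
            if r.qStarts[i] + r.blockSizes[i] > r.qStarts[i + 1]:
                bad("query blocks overlap or are out of order")
        if not (0 <= r.qStart < r.qEnd <= r.qSize):
            bad("qStart/qEnd outside [0, qSize]")
        if not (0 <= r.tStart < r.tEnd <= r.tSize):
            bad("tStart/tEnd outside [0, tSize]")
        if r.tStarts[0] != r.tStart or r.tStarts[-1] + r.blockSizes[-1] != r.tEnd:
            bad("tStart/tEnd disagree with block list")
        if r.qStarts[-1] + r.blockSizes[-1] > r.qSize:
            bad("query blocks exceed qSize")
        if r.strand == "+":
            span_ok = r.qStarts[0] == r.qStart and r.qStarts[-1] + r.blockSizes[-1] == r.qEnd
        else:
            span_ok = (
                r.qSize - (r.qStarts[-1] + r.blockSizes[-1]) == r.qStart
                and r.qSize - r.qStarts[0] == r.qEnd
            )
        if not span_ok:
            bad("qStart/qEnd disagree with block list for this strand")
        if any(c < 0 for c in (r.matches, r.misMatches, r.repMatches, r.nCount,
                               r.qNumInsert, r.qBaseInsert, r.tNumInsert, r.tBaseInsert)):
            bad("negative count field")

    def to_line(self) -> str:
        def commas(values: List[int]) -> str:
            return "".join(f"{v}," for v in values)

        fields = [
            self.matches, self.misMatches, self.repMatches, self.nCount,
            self.qNumInsert, self.qBaseInsert, self.tNumInsert, self.tBaseInsert,
            self.strand, self.qName, self.qSize, self.qStart, self.qEnd,
            self.tName, self.tSize, self.tStart, self.tEnd, self.blockCount,
            commas(self.blockSizes), commas(self.qStarts), commas(self.tStarts),
        ]
        return "\t".join(str(f) for f in fields) + "\n"

    @classmethod
    def from_line(cls, line: str) -> "PslRecord":
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 21:
            raise PslValidationError(f"expected 21 tab-separated columns, got {len(cols)}")

        def ints(col: str) -> List[int]:
            return [int(x) for x in col.split(",") if x != ""]

        return cls(
            matches=int(cols[0]), misMatches=int(cols[1]), repMatches=int(cols[2]),
            nCount=int(cols[3]), qNumInsert=int(cols[4]), qBaseInsert=int(cols[5]),
            tNumInsert=int(cols[6]), tBaseInsert=int(cols[7]), strand=cols[8],
            qName=cols[9], qSize=int(cols[10]), qStart=int(cols[11]), qEnd=int(cols[12]),
            tName=cols[13], tSize=int(cols[14]), tStart=int(cols[15]), tEnd=int(cols[16]),
            blockCount=int(cols[17]), blockSizes=ints(cols[18]),
            qStarts=ints(cols[19]), tStarts=ints(cols[20]),
        )


def write_psl(records: Iterable[PslRecord], header: bool = False) -> str:
    """Render records as PSL text; validates every record first.

    Output is a pure function of the record sequence: 21 tab-separated
    columns per line, list columns comma-joined with a trailing comma, and
    an optional 5-line header emitted exactly once at the top.
    """
    out = io.StringIO()
    if header:
        out.write(PSL_HEADER)
    for rec in records:
        rec.validate()
        out.write(rec.to_line())
    return out.getvalue()


def parse_psl(text: str) -> List[PslRecord]:
    """Parse PSL text (with or without the 5-line header) into records."""
    lines = text.split("\n")
    if lines and lines[0].startswith("psLayout"):
        lines = lines[5:]
    return [PslRecord.from_line(ln) for ln in lines if ln.strip()]
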