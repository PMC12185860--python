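"""Streaming readers and writers for FASTA/FASTQ, GFA1 and PAF.

All readers accept plain or gzip-compressed files (sniffed from the magic
bytes, never from the extension).  FASTA/FASTQ parsing is delegated to
Biopython's raw-string iterators so that headers, case and non-ACGT
characters round-trip byte-for-byte; GFA1 (miniasm-style S/L lines) and PAF
(minimap2 output) are simple line-oriented formats parsed here directly.

Coordinates follow the PAF convention throughout: 0-based, half-open on the
target.  They are never converted to 1-based internally.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Literal

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

GZIP_MAGIC = b"\x1f\x8b"

__all__ = [
    "ReadRecord",
    "MappingRecord",
    "GfaSegment",
    "GfaLink",
    "ContigGraph",
    "FormatError",
    "read_sequences",
    "write_sequences",
    "parse_gfa",
    "parse_paf",
    "open_text",
]


class FormatError(ValueError):
    """Raised for malformed FASTA/FASTQ/GFA/PAF input."""


@dataclass(frozen=True)
class ReadRecord:
    """One sequence record: the unit being reordered.

    ``id`` is the first whitespace-delimited token of the header;
    ``description`` is the remainder (may be empty).  ``quality`` is present
    iff the record came from FASTQ and always matches the sequence length.
    """

    id: str
    sequence: str
    description: str = ""
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("record with empty id")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    @property
    def header(self) -> str:
        return f"{self.id} {self.description}" if self.description else self.id


@dataclass(frozen=True)
class MappingRecord:
    """One PAF alignment row (mandatory columns we act on).

    ``t_start``/``t_end`` are 0-based half-open positions on the contig;
    ``n_match`` is PAF column 10 (number of residue matches).
    ``is_primary`` is False only for rows tagged tp:A:S or tp:A:I.
    """

    read_id: str
    read_len: int
    strand: str
    contig_id: str
    contig_len: int
    t_start: int
    t_end: int
    n_match: int
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r} for read {self.read_id!r}")
        if not (0 <= self.t_start < self.t_end <= self.contig_len):
            raise FormatError(
                f"read {self.read_id!r}: target interval [{self.t_start}, "
                f"{self.t_end}) outside contig of length {self.contig_len}"
            )
        if self.n_match < 0:
            raise FormatError(f"read {self.read_id!r}: negative match count")


@dataclass(frozen=True)
class GfaSegment:
    """A GFA S line: one contig/unitig, with or without its sequence."""

    id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.length:
            raise FormatError(
                f"segment {self.id!r}: declared length {self.length} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class GfaLink:
    """A GFA L line: an oriented overlap between two segments."""

    from_id: str
    from_orient: str
    to_id: str
    to_orient: str
    overlap_len: int = 0


@dataclass
class ContigGraph:
    """Oriented segments plus directed oriented links, as parsed from GFA.

    ``adjacency`` maps an oriented node ``(segment_id, orient)`` to its
    deterministically ordered successor list; it is populated by
    :func:`seqorder.contig_graph.build_adjacency`, not by the parser.
    """

    segments: dict[str, GfaSegment] = field(default_factory=dict)
    links: list[GfaLink] = field(default_factory=list)
    adjacency: dict[tuple[str, str], list[tuple[str, str]]] | None = None

    @property
    def n_segments(self) -> int:
        return len(self.segments)


# ---------------------------------------------------------------------------
# transparent-gzip plumbing


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open ``path`` as text, transparently decompressing gzip on read.

    Writing: a ``.gz`` suffix selects gzip output (writers cannot sniff).
    """
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as probe:
            magic = probe.read(2)
        if magic == GZIP_MAGIC:
            return gzip.open(path, "rt")
        return open(path, "rt")
    if path.suffix == ".gz":
        return gzip.open(path, mode if "t" in mode else mode + "t")
    return open(path, mode if "t" in mode else mode + "t")


def _as_text_stream(source: str | Path | IO) -> tuple[IO[str], bool]:
    """Return (text stream, we_opened_it)."""
    if isinstance(source, (str, Path)):
        return open_text(source), True
    if isinstance(source, io.TextIOBase):
        return source, False
    # binary stream: wrap (no gzip sniffing on raw streams)
    return io.TextIOWrapper(source), False


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _split_title(title: str) -> tuple[str, str]:
    parts = title.split(None, 1)
    if not parts:
        raise FormatError("empty sequence header")
    return parts[0], parts[1] if len(parts) == 2 else ""


def sniff_format(stream: IO[str]) -> str | None:
    """Peek the first non-blank character: '>' fasta, '@' fastq, None empty."""
    pos = stream.tell()
    first = None
    while True:
        ch = stream.read(1)
        if not ch:
            break
        if not ch.isspace():
            first = ch
            break
    stream.seek(pos)
    if first is None:
        return None
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise FormatError(f"cannot determine format from leading character {first!r}")


def read_sequences(
    source: str | Path | IO,
    format_hint: Literal["auto", "fasta", "fastq"] = "auto",
) -> Iterator[ReadRecord]:
    """Lazily yield :class:`ReadRecord` in file order.

    An empty file yields nothing.  Malformed records raise
    :class:`FormatError` naming the approximate line.
    """
    stream, close = _as_text_stream(source)
    try:
        fmt = format_hint
        if fmt == "auto":
            sniffed = sniff_format(stream)
            if sniffed is None:
                return
            fmt = sniffed
        if fmt == "fasta":
            for title, seq in SimpleFastaParser(stream):
                rid, desc = _split_title(title)
                yield ReadRecord(rid, seq, desc)
        elif fmt == "fastq":
            n = 0
            try:
                for title, seq, qual in FastqGeneralIterator(stream):
                    rid, desc = _split_title(title)
                    if len(qual) != len(seq):
                        raise FormatError(
                            f"fastq record {rid!r} near line {4 * n + 1}: "
                            f"quality/sequence length mismatch"
                        )
                    yield ReadRecord(rid, seq, desc, quality=qual)
                    n += 1
            except ValueError as exc:  # Biopython's truncation/format errors
                if isinstance(exc, FormatError):
                    raise
                raise FormatError(
                    f"malformed fastq near line {4 * n + 1}: {exc}"
                ) from exc
        else:
            raise ValueError(f"unknown format {fmt!r}")
    finally:
        if close:
            stream.close()


def write_sequences(
    records: Iterable[ReadRecord],
    dest: str | Path | IO[str],
    format: Literal["fasta", "fastq"] = "fasta",
    line_width: int | None = None,
) -> int:
    """Write records; return the count.  Round-trips all four fields.

    ``line_width`` wraps FASTA sequence lines (presentation only); FASTQ is
    always 4-line.  FASTQ output requires every record to carry a quality
    string.
    """
    if isinstance(dest, (str, Path)):
        stream: IO[str] = open_text(dest, "wt")
        close = True
    else:
        stream, close = dest, False
    n = 0
    try:
        for rec in records:
            if format == "fasta":
                stream.write(f">{rec.header}\n")
                if line_width:
                    for i in range(0, len(rec.sequence), line_width):
                        stream.write(rec.sequence[i : i + line_width] + "\n")
                    if not rec.sequence:
                        stream.write("\n")
                else:
                    stream.write(rec.sequence + "\n")
            elif format == "fastq":
                if rec.quality is None:
                    raise ValueError(
                        f"fastq output requested but record {rec.id!r} has no quality"
                    )
                stream.write(f"@{rec.header}\n{rec.sequence}\n+\n{rec.quality}\n")
            else:
                raise ValueError(f"unknown format {format!r}")
            n += 1
    finally:
        if close:
            stream.close()
    return n


# ---------------------------------------------------------------------------
# GFA1

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def _overlap_from_cigar(cigar: str, line_no: int) -> int:
    """Sum of M-operation lengths; '*' means unknown → 0."""
    if cigar == "*":
        return 0
    pos = 0
    total = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise FormatError(f"GFA line {line_no}: bad CIGAR {cigar!r}")
        if m.group(2) == "M":
            total += int(m.group(1))
        pos = m.end()
    if pos != len(cigar):
        raise FormatError(f"GFA line {line_no}: bad CIGAR {cigar!r}")
    return total


def _tag_value(fields: list[str], name: str, typ: str) -> str | None:
    prefix = f"{name}:{typ}:"
    for f in fields:
        if f.startswith(prefix):
            return f[len(prefix) :]
    return None


def parse_gfa(source: str | Path | IO, strict: bool = True) -> ContigGraph:
    """Parse GFA1 S and L lines into a :class:`ContigGraph`.

    Other record types (H, A, C, P …) are ignored with a debug log.  In
    strict mode a link naming an undeclared segment is an error; lenient
    mode synthesizes a length-0 placeholder segment with a warning.
    """
    stream, close = _as_text_stream(source)
    graph = ContigGraph()
    pending_links: list[tuple[GfaLink, int]] = []
    try:
        for line_no, line in enumerate(stream, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            kind = line[0]
            if kind == "S":
                fields = line.split("\t")
                if len(fields) < 3:
                    raise FormatError(f"GFA line {line_no}: S line needs 3 fields")
                seg_id, seq = fields[1], fields[2]
                if seq == "*":
                    ln = _tag_value(fields[3:], "LN", "i")
                    if ln is None:
                        raise FormatError(
                            f"GFA line {line_no}: segment {seg_id!r} has '*' "
                            f"sequence and no LN:i tag"
                        )
                    graph.segments[seg_id] = GfaSegment(seg_id, int(ln))
                else:
                    graph.segments[seg_id] = GfaSegment(seg_id, len(seq), seq)
            elif kind == "L":
                fields = line.split("\t")
                if len(fields) < 6:
                    raise FormatError(f"GFA line {line_no}: L line needs 6 fields")
                _, fid, fo, tid, to, cigar = fields[:6]
                if fo not in "+-" or to not in "+-":
                    raise FormatError(f"GFA line {line_no}: bad orientation")
                link = GfaLink(fid, fo, tid, to, _overlap_from_cigar(cigar, line_no))
                pending_links.append((link, line_no))
            else:
                logger.debug("ignoring GFA record type %r at line %d", kind, line_no)
    finally:
        if close:
            stream.close()
    for link, line_no in pending_links:
        for seg_id in (link.from_id, link.to_id):
            if seg_id not in graph.segments:
                if strict:
                    raise FormatError(
                        f"GFA line {line_no}: link references undeclared "
                        f"segment {seg_id!r}"
                    )
                logger.warning(
                    "link at line %d references undeclared segment %r; "
                    "synthesizing length-0 segment",
                    line_no,
                    seg_id,
                )
                graph.segments[seg_id] = GfaSegment(seg_id, 0, None)
        graph.links.append(link)
    return graph


# ---------------------------------------------------------------------------
# PAF


def parse_paf(
    source: str | Path | IO,
    keep: Literal["primary_only", "all"] = "primary_only",
) -> Iterator[MappingRecord]:
    """Lazily yield PAF rows as :class:`MappingRecord`.

    With ``keep='primary_only'`` rows tagged tp:A:S (secondary) or tp:A:I
    (inversion) are dropped; rows without a tp tag are kept.
    """
    stream, close = _as_text_stream(source)
    try:
        for line_no, line in enumerate(stream, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"PAF line {line_no}: expected >= 12 columns, got {len(fields)}"
                )
            try:
                read_len = int(fields[1])
                contig_len = int(fields[6])
                t_start = int(fields[7])
                t_end = int(fields[8])
                n_match = int(fields[9])
            except ValueError as exc:
                raise FormatError(f"PAF line {line_no}: non-integer field: {exc}") from exc
            tp = _tag_value(fields[12:], "tp", "A")
            is_primary = tp not in ("S", "I")
            if keep == "primary_only" and not is_primary:
                continue
            yield MappingRecord(
                read_id=fields[0],
                read_len=read_len,
                strand=fields[4],
                contig_id=fields[5],
                contig_len=contig_len,
                t_start=t_start,
                t_end=t_end,
                n_match=n_match,
                is_primary=is_primary,
            )
    finally:
        if close:
            stream.close()


def format_paf_line(m: MappingRecord) -> str:
    """Render a 12-column PAF line (query coordinates as full-length)."""
    cols = [
        m.read_id,
        str(m.read_len),
        "0",
        str(m.read_len),
        m.strand,
        m.contig_id,
        str(m.contig_len),
        str(m.t_start),
        str(m.t_end),
        str(m.n_match),
        str(m.t_end - m.t_start),
        "255",
    ]
    if not m.is_primary:
        cols.append("tp:A:S")
    return "\t".join(cols)


def check_unique_ids(
    records: Iterable[ReadRecord], allow_duplicates: bool = False
) -> Iterator[ReadRecord]:
    """Pass records through, rejecting duplicate ids (or suffixing them).

    With ``allow_duplicates`` the second copy of id X becomes ``X#dup2`` and
    so on; callers strip the suffix again on output.
    """
    seen: dict[str, int] = {}
    for rec in records:
        count = seen.get(rec.id, 0) + 1
        seen[rec.id] = count
        if count == 1:
            yield rec
        elif allow_duplicates:
            yield replace(rec, id=f"{rec.id}#dup{count}")
        else:
            raise FormatError(
                f"duplicate read id {rec.id!r}; pass allow_duplicates to "
                f"suffix duplicates instead"
            )


def strip_duplicate_suffix(read_id: str) -> str:
    """Undo the ``#dupN`` suffix added by :func:`check_unique_ids`."""
    base, sep, tail = read_id.rpartition("#dup")
    if sep and tail.isdigit():
        return base
    return read_id
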