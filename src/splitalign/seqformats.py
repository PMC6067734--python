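"""Streaming FASTQ/FASTA parsing with byte-offset awareness.

The parsers here are deliberately hand-rolled rather than delegated to a
generic sequence-IO library: the split planner needs to know the exact byte
offset of every record header so that a task can start reading mid-file, and
serialization must be byte-stable so that piping records to an external
aligner is equivalent to handing it the original file.

FASTQ is treated as the strict 4-line dialect (header / bases / '+' separator
/ qualities); multi-line FASTQ is rejected because boundary synchronization
is only well-defined under 4-line periodicity.  FASTA sequences may wrap over
any number of lines on input but are serialized unwrapped.
"""

from __future__ import annotations

import bz2
import gzip
import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import BinaryIO, Iterator, Optional, Tuple, Union

__all__ = [
    "CodecKind",
    "SeqFormat",
    "SequenceRecord",
    "FormatError",
    "detect_codec",
    "open_decompressed",
    "parse_fastq",
    "parse_fasta",
    "parse_records",
    "parse_with_offsets",
    "serialize_record",
    "revcomp",
]


class FormatError(ValueError):
    """A FASTQ/FASTA stream violates the format at a known line."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class CodecKind(Enum):
    """Compression codec of an input file, decided by magic bytes only."""

    PLAIN = "plain"
    GZIP = "gzip"
    BZIP2 = "bzip2"


class SeqFormat(Enum):
    FASTQ = "fastq"
    FASTA = "fasta"


@dataclass(frozen=True)
class SequenceRecord:
    """One sequencing read.

    ``read_id`` is the header up to the first whitespace, without the leading
    sigil; ``description`` is the remainder of the header (possibly empty).
    FASTQ records carry a quality string of the same length as the bases;
    FASTA records carry none.
    """

    read_id: str
    description: str
    bases: str
    qualities: Optional[str]
    source_format: SeqFormat

    def __post_init__(self) -> None:
        if not self.read_id:
            raise FormatError("empty read identifier")
        if self.source_format is SeqFormat.FASTQ:
            if self.qualities is None:
                raise FormatError(f"FASTQ record {self.read_id!r} lacks qualities")
            if len(self.qualities) != len(self.bases):
                raise FormatError(
                    f"record {self.read_id!r}: {len(self.qualities)} quality "
                    f"characters vs {len(self.bases)} bases"
                )
        elif self.qualities is not None:
            raise FormatError(f"FASTA record {self.read_id!r} carries qualities")

    @property
    def header(self) -> str:
        return f"{self.read_id} {self.description}" if self.description else self.read_id


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet, case-preserving."""
    return seq.translate(_COMPLEMENT)[::-1]


_GZIP_MAGIC = b"\x1f\x8b"
_BZIP2_MAGIC = b"BZh"


def detect_codec(path: Union[str, Path]) -> CodecKind:
    """Detect the compression codec of *path* from its magic bytes.

    Extensions are never consulted.  Raises ``OSError`` naming the path for
    unreadable or empty files.
    """
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            head = fh.read(3)
    except OSError as exc:
        raise OSError(f"cannot read {path}: {exc}") from exc
    if not head:
        raise OSError(f"cannot detect codec of empty file {path}")
    if head[:2] == _GZIP_MAGIC:
        return CodecKind.GZIP
    if head == _BZIP2_MAGIC:
        return CodecKind.BZIP2
    return CodecKind.PLAIN


def open_decompressed(path: Union[str, Path], codec: Optional[CodecKind] = None) -> BinaryIO:
    """Open *path* as a decompressed binary stream."""
    path = Path(path)
    if codec is None:
        codec = detect_codec(path)
    if codec is CodecKind.GZIP:
        return gzip.open(path, "rb")  # type: ignore[return-value]
    if codec is CodecKind.BZIP2:
        return bz2.open(path, "rb")  # type: ignore[return-value]
    return open(path, "rb")


def _lines_with_offsets(stream: BinaryIO, initial_offset: int) -> Iterator[Tuple[int, bytes]]:
    # Binary file iteration yields lines including their b'\n'; the final
    # line may lack one.  Offsets are maintained by summing raw line lengths.
    offset = initial_offset
    for raw in stream:
        yield offset, raw
        offset += len(raw)


def _decode(raw: bytes, line_number: int) -> str:
    # \r\n tolerated on input; \r stripped.
    return raw.rstrip(b"\r\n").decode("ascii", errors="strict")


def parse_fastq_with_offsets(
    stream: BinaryIO, initial_offset: int = 0
) -> Iterator[Tuple[int, SequenceRecord]]:
    """Yield ``(header_byte_offset, record)`` from a 4-line FASTQ stream.

    The stream must be positioned at a record start.  Raises
    :class:`FormatError` with a line number on malformed input.
    """
    lines = _lines_with_offsets(stream, initial_offset)
    line_no = 0
    while True:
        try:
            offset, raw_header = next(lines)
        except StopIteration:
            return
        line_no += 1
        header = _decode(raw_header, line_no)
        if not header:
            # tolerate blank line(s) at end of file only
            for _, trailing in lines:
                if trailing.rstrip(b"\r\n"):
                    raise FormatError("blank line inside FASTQ", line_no)
            return
        if not header.startswith("@"):
            raise FormatError(f"FASTQ header must start with '@', got {header[:20]!r}", line_no)
        try:
            _, raw_bases = next(lines)
            line_no += 1
            bases = _decode(raw_bases, line_no)
            _, raw_sep = next(lines)
            line_no += 1
            sep = _decode(raw_sep, line_no)
            _, raw_quals = next(lines)
            line_no += 1
            quals = _decode(raw_quals, line_no)
        except StopIteration:
            raise FormatError("truncated FASTQ record", line_no) from None
        if not sep.startswith("+"):
            raise FormatError(f"FASTQ separator must start with '+', got {sep[:20]!r}", line_no - 1)
        if len(quals) != len(bases):
            raise FormatError(
                f"{len(quals)} quality characters vs {len(bases)} bases", line_no
            )
        read_id, _, description = header[1:].partition(" ")
        yield offset, SequenceRecord(
            read_id=read_id,
            description=description.strip(),
            bases=bases,
            qualities=quals,
            source_format=SeqFormat.FASTQ,
        )


def parse_fasta_with_offsets(
    stream: BinaryIO, initial_offset: int = 0
) -> Iterator[Tuple[int, SequenceRecord]]:
    """Yield ``(header_byte_offset, record)`` from a FASTA stream.

    Wrapped sequence lines are concatenated.  The first non-empty line must
    be a ``>`` header.
    """
    header: Optional[str] = None
    header_offset = 0
    chunks: list[str] = []
    line_no = 0

    def finish() -> Iterator[Tuple[int, SequenceRecord]]:
        assert header is not None
        read_id, _, description = header[1:].partition(" ")
        yield header_offset, SequenceRecord(
            read_id=read_id,
            description=description.strip(),
            bases="".join(chunks),
            qualities=None,
            source_format=SeqFormat.FASTA,
        )

    for offset, raw in _lines_with_offsets(stream, initial_offset):
        line_no += 1
        line = _decode(raw, line_no)
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                yield from finish()
            header = line
            header_offset = offset
            chunks = []
        else:
            if header is None:
                raise FormatError(
                    f"FASTA must begin with a '>' header, got {line[:20]!r}", line_no
                )
            chunks.append(line)
    if header is not None:
        yield from finish()


def parse_with_offsets(
    stream: BinaryIO, fmt: SeqFormat, initial_offset: int = 0
) -> Iterator[Tuple[int, SequenceRecord]]:
    if fmt is SeqFormat.FASTQ:
        return parse_fastq_with_offsets(stream, initial_offset)
    return parse_fasta_with_offsets(stream, initial_offset)


def parse_fastq(stream: BinaryIO) -> Iterator[SequenceRecord]:
    for _, rec in parse_fastq_with_offsets(stream):
        yield rec


def parse_fasta(stream: BinaryIO) -> Iterator[SequenceRecord]:
    for _, rec in parse_fasta_with_offsets(stream):
        yield rec


def parse_records(stream: BinaryIO, fmt: SeqFormat) -> Iterator[SequenceRecord]:
    for _, rec in parse_with_offsets(stream, fmt):
        yield rec


def serialize_record(record: SequenceRecord) -> bytes:
    """Serialize a record to its canonical byte form.

    FASTQ: four lines with a bare ``+`` separator.  FASTA: header plus one
    unwrapped sequence line.  ``parse(serialize(r))`` reproduces ``r``'s
    fields exactly.
    """
    header = record.header
    if record.source_format is SeqFormat.FASTQ:
        return f"@{header}\n{record.bases}\n+\n{record.qualities}\n".encode("ascii")
    return f">{header}\n{record.bases}\n".encode("ascii")
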