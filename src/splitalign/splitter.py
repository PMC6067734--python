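"""Byte-range split planning and record-boundary synchronization.

An input file is divided into contiguous byte-range splits so that each
parallel task can process one split.  Because a split boundary usually lands
mid-record, every split's start is *synchronized* forward to the first true
record header at or after it; a record is owned by the split in whose synced
half-open range its header byte offset falls.  This guarantees that the union
of all split streams reproduces the whole-file parse with no loss and no
duplication, for any split size.

Paired-end inputs come as two files with a strict one-to-one read
correspondence.  Byte-symmetric splitting of the two files silently breaks
when the files' records differ in byte length, so composite splits here are
built *by record ordinal*: the forward (left) file is byte-split, its
per-split ownership counts are computed, and the reverse (right) file's split
points are located by streaming to the same ordinals.  The one-to-one
invariant then holds unconditionally.

Compressed inputs (gzip/bzip2) are never byte-split: each compressed file is
a single split, since random access into the compressed stream is not
possible for gzip and out of scope for bzip2.
"""

from __future__ import annotations

import io
import os
import re
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, List, Optional, Sequence, Tuple, Union

from .seqformats import (
    CodecKind,
    FormatError,
    SeqFormat,
    SequenceRecord,
    detect_codec,
    open_decompressed,
    parse_with_offsets,
    serialize_record,
)

__all__ = [
    "ByteSplit",
    "SyncedSplit",
    "CompositeSplit",
    "SplitError",
    "PairingError",
    "compute_split_size",
    "plan_splits",
    "sync_to_record_start",
    "sync_splits",
    "plan_synced_splits",
    "read_split",
    "pair_splits",
    "read_composite",
    "pair_stem",
    "manifest_lines",
]


class SplitError(ValueError):
    pass


class PairingError(ValueError):
    """The two files of a paired-end dataset are out of correspondence."""


@dataclass(frozen=True)
class ByteSplit:
    """A half-open byte range ``[start, end)`` of one input file.

    An empty range (``start == end``) is legal only for ordinal-derived
    right-file splits whose left counterpart owns no records.
    """

    path: Path
    start: int
    end: int
    codec: CodecKind
    index: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise SplitError(f"invalid byte range [{self.start}, {self.end})")


@dataclass(frozen=True)
class SyncedSplit:
    """A byte split whose start has been synchronized to a record boundary.

    ``first_record_offset`` is the offset of the first record header at or
    after ``base.start`` (equal to ``base.end`` or beyond means the split
    owns no records); ``record_count`` is the number of records owned.
    """

    base: ByteSplit
    first_record_offset: int
    record_count: int

    def __post_init__(self) -> None:
        if self.first_record_offset < self.base.start:
            raise SplitError("synced start precedes the split start")


@dataclass(frozen=True)
class CompositeSplit:
    """Paired forward/reverse splits owning the same read ordinals."""

    left: SyncedSplit
    right: SyncedSplit
    index: int

    def __post_init__(self) -> None:
        if self.left.record_count != self.right.record_count:
            raise PairingError(
                f"composite {self.index}: {self.left.record_count} forward vs "
                f"{self.right.record_count} reverse records"
            )


def compute_split_size(total_bytes: int, n_tasks: int) -> int:
    """Split size yielding at most *n_tasks* splits over *total_bytes*."""
    if total_bytes < 1 or n_tasks < 1:
        raise ValueError(
            f"total_bytes and n_tasks must be positive, got {total_bytes}, {n_tasks}"
        )
    return -(-total_bytes // n_tasks)


def plan_splits(
    path: Union[str, Path], codec: CodecKind, split_size: int
) -> List[ByteSplit]:
    """Plan byte splits over *path*.

    Plain files are cut into consecutive ``split_size`` ranges; compressed
    files are a single whole-file split.
    """
    path = Path(path)
    size = os.path.getsize(path)
    if size == 0:
        raise ValueError(f"cannot split empty file {path}")
    if split_size < 1:
        raise ValueError(f"split_size must be >= 1, got {split_size}")
    if codec is not CodecKind.PLAIN:
        return [ByteSplit(path=path, start=0, end=size, codec=codec, index=0)]
    splits = []
    for k, start in enumerate(range(0, size, split_size)):
        splits.append(
            ByteSplit(path=path, start=start, end=min(start + split_size, size),
                      codec=codec, index=k)
        )
    return splits


def _line_starts_from(fh, offset: int) -> Iterator[Tuple[int, bytes]]:
    # Yield (line_start_offset, raw_line) for every line starting at or after
    # `offset`.  `offset` itself is a line start iff it is 0 or preceded by \n.
    if offset == 0:
        pos = 0
        fh.seek(0)
    else:
        fh.seek(offset - 1)
        if fh.read(1) == b"\n":
            pos = offset
        else:
            partial = fh.readline()  # remainder of the interrupted line
            pos = offset + len(partial)
        fh.seek(pos)
    for raw in fh:
        yield pos, raw
        pos += len(raw)


def sync_to_record_start(
    path: Union[str, Path], offset: int, fmt: SeqFormat
) -> int:
    """Smallest byte offset >= *offset* that begins a record header line.

    Returns the file size when no record starts at or after *offset*.  FASTA
    headers are lines starting ``>``.  A FASTQ candidate line L starting
    ``@`` is accepted iff line L+2 starts ``+`` and lines L+1 and L+3 have
    equal content length — this rejects quality lines that begin with ``@``,
    because the line two below a quality line is a bases line, which can
    never start ``+``.
    """
    path = Path(path)
    size = os.path.getsize(path)
    if offset < 0 or offset > size:
        raise ValueError(f"offset {offset} outside [0, {size}]")
    if offset >= size:
        return size
    with open(path, "rb") as fh:
        lines = _line_starts_from(fh, offset)
        if fmt is SeqFormat.FASTA:
            for pos, raw in lines:
                if raw.startswith(b">"):
                    return pos
            return size
        window: deque[Tuple[int, bytes]] = deque()
        exhausted = False
        while True:
            while not exhausted and len(window) < 4:
                try:
                    window.append(next(lines))
                except StopIteration:
                    exhausted = True
            if not window:
                return size
            pos, raw = window[0]
            if raw.startswith(b"@") and len(window) >= 4:
                l1 = window[1][1].rstrip(b"\r\n")
                l2 = window[2][1]
                l3 = window[3][1].rstrip(b"\r\n")
                if l2.startswith(b"+") and len(l1) == len(l3):
                    return pos
            window.popleft()


def sync_splits(splits: Sequence[ByteSplit], fmt: SeqFormat) -> List[SyncedSplit]:
    """Synchronize every split of one file and count owned records.

    One streaming pass over the file assigns each record header offset to the
    split whose synced half-open range contains it.
    """
    if not splits:
        return []
    path = splits[0].path
    codec = splits[0].codec
    if codec is not CodecKind.PLAIN:
        if len(splits) != 1:
            raise SplitError("compressed files must be single-split")
        with open_decompressed(path, codec) as fh:
            count = sum(1 for _ in parse_with_offsets(fh, fmt))
        return [SyncedSplit(base=splits[0], first_record_offset=0, record_count=count)]

    sync_points = [sync_to_record_start(path, sp.start, fmt) for sp in splits]
    size = os.path.getsize(path)
    sync_points.append(size)  # sentinel: sync(end of last) capped at size
    counts = [0] * len(splits)
    bucket = 0
    with open(path, "rb") as fh:
        for header_offset, _rec in parse_with_offsets(fh, fmt):
            while bucket + 1 < len(splits) and header_offset >= sync_points[bucket + 1]:
                bucket += 1
            # header_offset < sync_points[bucket] cannot occur for bucket 0
            # on a well-formed file (offset 0 is a record start).
            counts[bucket] += 1
    return [
        SyncedSplit(base=sp, first_record_offset=pt, record_count=c)
        for sp, pt, c in zip(splits, sync_points[:-1], counts)
    ]


def plan_synced_splits(
    path: Union[str, Path], fmt: SeqFormat, split_size: int,
    codec: Optional[CodecKind] = None,
) -> List[SyncedSplit]:
    """Convenience: plan, synchronize and count in one call."""
    path = Path(path)
    if codec is None:
        codec = detect_codec(path)
    return sync_splits(plan_splits(path, codec, split_size), fmt)


def read_split(
    split: SyncedSplit, fmt: SeqFormat
) -> Iterator[Tuple[int, SequenceRecord]]:
    """Stream the records owned by *split* as ``(key, record)`` pairs.

    The key is the 0-based ordinal of the record within the split.  Reading
    is streaming: memory is bounded by one record, not by the split size.
    A record whose header lies inside the split but whose body extends past
    ``base.end`` is still owned and read in full.
    """
    base = split.base
    if base.codec is not CodecKind.PLAIN:
        with open_decompressed(base.path, base.codec) as fh:
            for key, (_off, rec) in enumerate(parse_with_offsets(fh, fmt)):
                yield key, rec
        return
    if split.first_record_offset >= base.end and base.start != base.end:
        return
    if base.start == base.end:  # empty ordinal-derived range
        return
    with open(base.path, "rb") as fh:
        fh.seek(split.first_record_offset)
        key = 0
        try:
            for header_offset, rec in parse_with_offsets(
                fh, fmt, initial_offset=split.first_record_offset
            ):
                if header_offset >= base.end:
                    break
                yield key, rec
                key += 1
        except FormatError as exc:
            raise FormatError(
                f"split {base.index} of {base.path}, record {key}: {exc}"
            ) from exc


_PAIR_SUFFIX = re.compile(r"/[12]$")


def pair_stem(record: SequenceRecord) -> str:
    """Read-id stem shared by the two ends of a pair.

    Strips a trailing ``/1``/``/2`` from the id; Casava-style ids carry the
    end number in the description (``1:N:0:...``), so the id itself is
    already the stem.
    """
    return _PAIR_SUFFIX.sub("", record.read_id)


def _ordinal_boundaries(
    path: Path, fmt: SeqFormat, ordinals: Sequence[int], total: int
) -> List[int]:
    # Byte offset of record `c` for each c in `ordinals` (sorted), with
    # offset = file size for c == total.  Single streaming pass.
    size = os.path.getsize(path)
    out: List[int] = []
    wanted = iter(ordinals)
    try:
        target = next(wanted)
    except StopIteration:
        return out
    idx = 0
    with open(path, "rb") as fh:
        for header_offset, _rec in parse_with_offsets(fh, fmt):
            while target == idx:
                out.append(header_offset)
                try:
                    target = next(wanted)
                except StopIteration:
                    return out
            idx += 1
    while True:
        if target == total:
            out.append(size)
        else:  # pragma: no cover - guarded by count check in pair_splits
            raise PairingError(f"ordinal {target} beyond file with {total} records")
        try:
            target = next(wanted)
        except StopIteration:
            return out


def _whole_file_split(splits: Sequence[SyncedSplit]) -> SyncedSplit:
    first = splits[0].base
    last = splits[-1].base
    base = ByteSplit(path=first.path, start=0, end=last.end, codec=first.codec, index=0)
    return SyncedSplit(
        base=base,
        first_record_offset=splits[0].first_record_offset,
        record_count=sum(s.record_count for s in splits),
    )


def pair_splits(
    left: Sequence[SyncedSplit],
    right: Sequence[SyncedSplit],
    verify_ids: bool = False,
) -> List[CompositeSplit]:
    """Pair forward-file splits with ordinal-aligned reverse-file splits.

    The left file's ownership counts define cumulative ordinal boundaries;
    the right file's split points are located by streaming to those same
    ordinals, so composite *i* owns identical record ordinals in both files
    regardless of byte-layout differences.  If either file is compressed the
    pairing collapses to a single whole-file composite.

    ``verify_ids=True`` additionally streams every composite and checks that
    the paired ids share a stem (an opt-in safety net, off by default).
    """
    if not left or not right:
        raise PairingError("empty split list")
    n_left = sum(s.record_count for s in left)
    n_right = sum(s.record_count for s in right)
    if n_left != n_right:
        raise PairingError(
            f"paired files disagree: {n_left} forward vs {n_right} reverse records"
        )

    left_codec = left[0].base.codec
    right_codec = right[0].base.codec
    if left_codec is not CodecKind.PLAIN or right_codec is not CodecKind.PLAIN:
        composites = [
            CompositeSplit(left=_whole_file_split(left), right=_whole_file_split(right), index=0)
        ]
    else:
        right_path = right[0].base.path
        right_fmt = _sniff_format(right_path, right_codec)
        cum = [0]
        for s in left:
            cum.append(cum[-1] + s.record_count)
        offsets = _ordinal_boundaries(right_path, right_fmt, cum, n_right)
        composites = []
        for i, lsplit in enumerate(left):
            start = 0 if i == 0 else offsets[i]
            end = offsets[i + 1]
            rbase = ByteSplit(
                path=right_path, start=start, end=end, codec=right_codec, index=i
            )
            rsplit = SyncedSplit(
                base=rbase,
                first_record_offset=offsets[i],
                record_count=lsplit.record_count,
            )
            composites.append(CompositeSplit(left=lsplit, right=rsplit, index=i))

    if verify_ids:
        left_fmt = _sniff_format(left[0].base.path, left_codec)
        for comp in composites:
            rstream = read_split(comp.right, _sniff_format(comp.right.base.path, right_codec))
            for (j, lrec), (_, rrec) in zip(read_split(comp.left, left_fmt), rstream):
                if pair_stem(lrec) != pair_stem(rrec):
                    raise PairingError(
                        f"composite {comp.index}, pair {j}: id stems differ "
                        f"({lrec.read_id!r} vs {rrec.read_id!r})"
                    )
    return composites


def _sniff_format(path: Path, codec: CodecKind) -> SeqFormat:
    with open_decompressed(path, codec) as fh:
        first = fh.read(1)
    if first == b">":
        return SeqFormat.FASTA
    return SeqFormat.FASTQ


def read_composite(
    split: CompositeSplit, fmt: Optional[SeqFormat] = None
) -> Iterator[Tuple[int, bytes]]:
    """Stream a composite split as ``(key, merged)`` pairs.

    ``merged`` is the serialized forward record immediately followed by the
    serialized reverse record; ``key`` is the byte length of the forward
    part, so slicing ``merged`` at ``key`` recovers both ends exactly.
    """
    if fmt is None:
        fmt = _sniff_format(split.left.base.path, split.left.base.codec)
    left_iter = read_split(split.left, fmt)
    right_iter = read_split(split.right, fmt)
    j = 0
    while True:
        lrec = next(left_iter, None)
        rrec = next(right_iter, None)
        if lrec is None and rrec is None:
            return
        if lrec is None or rrec is None:
            side = "forward" if lrec is None else "reverse"
            raise PairingError(
                f"composite {split.index}: {side} side exhausted at pair {j}"
            )
        lbytes = serialize_record(lrec[1])
        rbytes = serialize_record(rrec[1])
        yield len(lbytes), lbytes + rbytes
        j += 1


def manifest_lines(splits: Sequence[SyncedSplit]) -> List[str]:
    """Plain-text split manifest for debugging: one split per line."""
    return [
        f"{s.base.path}\t{s.base.start}\t{s.base.end}\t"
        f"{s.first_record_offset}\t{s.record_count}"
        for s in splits
    ]
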