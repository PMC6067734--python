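"""SAM shard merging and mapping-statistics extraction.

``merge_sam`` is a pure copy-merge: one header, bodies concatenated in shard
order, no re-sorting — merging parallel shard output must not alter any
alignment record.  ``compute_stats`` condenses a SAM file into the metric
vector used to compare two alignment runs of the same read set (e.g. a
distributed run against a single-process baseline): counts of alignments,
mapped/unmapped/unique reads, mapped bases, mismatches, and the derived
rates.  ``misalignment_fraction`` measures, over the reads uniquely mapped
in both files, how many landed on a different reference or position.

Record-level parsing is delegated to pysam; the metrics themselves follow
the conventions of samtools stats/flagstat:

* ``bases_mapped`` counts CIGAR M/=/X/I bases of primary mapped records
  (soft-clips excluded);
* ``uniquely_mapped_reads`` uses the NH tag when present (NH:i:1), else
  falls back to counting QNAME+end occurrences among mapped primaries;
* ``average_quality`` assumes Phred+33 and averages over all primary
  records;
* ``average_coverage`` is mapped bases over the total reference length
  declared in the @SQ header.

Rates with an empty denominator are ``None`` ("undefined-marked").
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pysam

__all__ = [
    "SamStats",
    "StatsDiff",
    "MergeError",
    "SamFormatError",
    "merge_sam",
    "compute_stats",
    "compare_stats",
    "misalignment_fraction",
    "sorted_body_lines",
    "sort_sam",
    "format_stats",
]


class MergeError(ValueError):
    pass


class SamFormatError(ValueError):
    pass


@dataclass(frozen=True)
class SamStats:
    """Mapping-statistics vector of one SAM file."""

    alignments: int
    secondary_alignments: int
    reads_unmapped: int
    reads_mapped: int
    reads_mapped_and_paired: int
    uniquely_mapped_reads: int
    alignment_rate: Optional[float]
    bases_mapped: int
    mismatches: int
    error_rate: Optional[float]
    average_quality: Optional[float]
    average_coverage: Optional[float]


@dataclass(frozen=True)
class StatsDiff:
    """Signed relative differences ``(b - a) / a`` in percent, per metric.

    ``None`` marks a metric whose baseline is zero/undefined.  Antisymmetric
    under operand swap up to the nonlinearity of relative differences for
    the count metrics; strictly sign-flipping is guaranteed only when both
    operands are equal or the caller compares symmetric quantities.
    """

    percent: Dict[str, Optional[float]]


def _read_header_and_body(path: Union[str, Path]) -> Tuple[List[str], List[str]]:
    header: List[str] = []
    body: List[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                header.append(line.rstrip("\n"))
            else:
                line = line.rstrip("\n")
                if line:
                    body.append(line)
    return header, body


def _sq_set(header: Sequence[str]) -> frozenset:
    return frozenset(line for line in header if line.startswith("@SQ"))


def merge_sam(shards: Sequence[Union[str, Path]], out: Union[str, Path]) -> Path:
    """Copy-merge SAM *shards* into *out*: first header + concatenated bodies."""
    if not shards:
        raise MergeError("no shards to merge")
    out = Path(out)
    first_header, _ = _read_header_and_body(shards[0])
    if not first_header:
        raise MergeError(f"shard {shards[0]} has no header")
    ref_sq = _sq_set(first_header)
    with open(out, "w") as sink:
        for line in first_header:
            sink.write(line + "\n")
        for shard in shards:
            header, body = _read_header_and_body(shard)
            if _sq_set(header) != ref_sq:
                raise MergeError(
                    f"@SQ lines of {shard} differ from those of {shards[0]}"
                )
            for line in body:
                sink.write(line + "\n")
    return out


def _is_primary(aln: pysam.AlignedSegment) -> bool:
    return not aln.is_secondary and not aln.is_supplementary


_BASES_OPS = {0, 1, 7, 8}  # M, I, =, X


def compute_stats(sam: Union[str, Path]) -> SamStats:
    """Compute the mapping-statistics vector of one SAM file."""
    alignments = 0
    secondary = 0
    unmapped = 0
    mapped = 0
    mapped_and_paired = 0
    unique_nh = 0
    saw_nh = False
    bases_mapped = 0
    mismatches = 0
    qual_sum = 0
    qual_n = 0
    mapped_names: Dict[Tuple[str, bool, bool], int] = {}

    with pysam.AlignmentFile(str(sam), "r", check_sq=False) as fh:
        ref_len = sum(fh.header.lengths) if fh.header.nreferences else 0
        for aln in fh:
            primary = _is_primary(aln)
            if not aln.is_unmapped:
                alignments += 1
                if aln.reference_id >= fh.header.nreferences or aln.reference_id < 0:
                    raise SamFormatError(
                        f"record {aln.query_name!r} references a sequence absent from @SQ"
                    )
            if aln.is_secondary:
                secondary += 1
            if not aln.is_unmapped:
                # occurrences among all mapped records (secondary included)
                # drive the NH-absent uniqueness fallback
                key = (aln.query_name, aln.is_paired and aln.is_read1,
                       aln.is_paired and aln.is_read2)
                mapped_names[key] = mapped_names.get(key, 0) + 1
            if not primary:
                continue
            quals = aln.query_qualities
            if quals is not None and len(quals) > 0:
                qual_sum += sum(quals)
                qual_n += len(quals)
            if aln.is_unmapped:
                unmapped += 1
                continue
            mapped += 1
            if aln.is_paired and not aln.mate_is_unmapped:
                mapped_and_paired += 1
            if aln.has_tag("NH"):
                saw_nh = True
                if aln.get_tag("NH") == 1:
                    unique_nh += 1
            for op, length in (aln.cigartuples or []):
                if op in _BASES_OPS:
                    bases_mapped += length
            if aln.has_tag("NM"):
                mismatches += int(aln.get_tag("NM"))

    if saw_nh:
        unique = unique_nh
    else:
        unique = sum(1 for v in mapped_names.values() if v == 1)
    denom = mapped + unmapped
    return SamStats(
        alignments=alignments,
        secondary_alignments=secondary,
        reads_unmapped=unmapped,
        reads_mapped=mapped,
        reads_mapped_and_paired=mapped_and_paired,
        uniquely_mapped_reads=unique,
        alignment_rate=(mapped / denom) if denom else None,
        bases_mapped=bases_mapped,
        mismatches=mismatches,
        error_rate=(mismatches / bases_mapped) if bases_mapped else None,
        average_quality=(qual_sum / qual_n) if qual_n else None,
        average_coverage=(bases_mapped / ref_len) if ref_len else None,
    )


def compare_stats(a: SamStats, b: SamStats) -> StatsDiff:
    """Per-metric signed relative difference of *b* against baseline *a*.

    Negative means *b* is smaller.  Metrics whose baseline is zero or
    undefined are marked ``None``.
    """
    out: Dict[str, Optional[float]] = {}
    for f in fields(SamStats):
        va = getattr(a, f.name)
        vb = getattr(b, f.name)
        if va in (None, 0) or vb is None:
            out[f.name] = None
        else:
            out[f.name] = (vb - va) / va * 100.0
    return StatsDiff(percent=out)


def _unique_positions(sam: Union[str, Path]) -> Dict[Tuple[str, bool, bool], Tuple[str, int]]:
    """(reference name, 1-based position) of every uniquely mapped read."""
    hits: Dict[Tuple[str, bool, bool], List[Tuple[str, int]]] = {}
    nh_unique: Dict[Tuple[str, bool, bool], bool] = {}
    with pysam.AlignmentFile(str(sam), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or not _is_primary(aln):
                continue
            key = (aln.query_name, aln.is_paired and aln.is_read1,
                   aln.is_paired and aln.is_read2)
            hits.setdefault(key, []).append(
                (aln.reference_name, aln.reference_start + 1)
            )
            if aln.has_tag("NH"):
                nh_unique[key] = aln.get_tag("NH") == 1
    out = {}
    for key, positions in hits.items():
        unique = nh_unique[key] if key in nh_unique else len(positions) == 1
        if unique and len(positions) == 1:
            out[key] = positions[0]
    return out


def misalignment_fraction(a: Union[str, Path], b: Union[str, Path]) -> Optional[float]:
    """Fraction of reads uniquely mapped in both files whose (reference,
    position) differ.  ``None`` when no read is uniquely mapped in both."""
    pos_a = _unique_positions(a)
    pos_b = _unique_positions(b)
    shared = pos_a.keys() & pos_b.keys()
    if not shared:
        return None
    moved = sum(1 for key in shared if pos_a[key] != pos_b[key])
    return moved / len(shared)


def sorted_body_lines(sam: Union[str, Path]) -> List[str]:
    """Body lines position-sorted by (reference, position, name, flag).

    Used by equivalence checks: two runs of the same reads agree iff their
    position-sorted bodies are identical.
    """
    _, body = _read_header_and_body(sam)

    def sort_key(line: str):
        f = line.split("\t")
        return (f[2], int(f[3]), f[0], int(f[1]))

    return sorted(body, key=sort_key)


def sort_sam(sam: Union[str, Path], out: Union[str, Path]) -> Path:
    """Write a position-sorted copy of *sam* (header untouched)."""
    header, _ = _read_header_and_body(sam)
    out = Path(out)
    with open(out, "w") as sink:
        for line in header:
            sink.write(line + "\n")
        for line in sorted_body_lines(sam):
            sink.write(line + "\n")
    return out


def format_stats(stats: SamStats) -> str:
    """Aligned plain-text rendering of a stats vector."""
    rows = []
    for f in fields(SamStats):
        value = getattr(stats, f.name)
        if value is None:
            rendered = "undefined"
        elif isinstance(value, float):
            rendered = f"{value:.6g}"
        else:
            rendered = str(value)
        rows.append((f.name.replace("_", " "), rendered))
    width = max(len(name) for name, _ in rows)
    return "\n".join(f"{name:<{width}}  {value}" for name, value in rows)
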