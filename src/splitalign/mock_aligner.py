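"""Deterministic exact-match mock aligner.

A stand-in child process for testing the pipe/orchestration machinery
against a genuine external executable: it reads FASTQ/FASTA from its input
path(s) — regular files or FIFOs, it cannot tell — and writes SAM to its
output path, exactly like a real aligner, but its "alignment" is a plain
leftmost exact-substring search.  Identical inputs give byte-identical SAM
regardless of how the process is invoked, which is what makes it usable as
an equivalence oracle for the IPC and engine layers.

Mapping rules per read: leftmost exact occurrence of the bases on the
forward strand of the first reference sequence containing one (FLAG 0);
otherwise the same search with the reverse complement (FLAG 16, SEQ/QUAL
stored reverse-complemented per SAM convention); otherwise unmapped
(FLAG 4, POS 0, CIGAR *).  Mapped records carry MAPQ 60, CIGAR <len>M,
NM:i:0 and NH:i:1.  In paired mode both ends are mapped independently and
the pair bits, mate strand/position, RNEXT "=" and TLEN are filled in.

Kept import-light (stdlib + seqformats only) so process start-up stays
cheap when many instances are launched.
"""

from __future__ import annotations

import argparse
import io
import sys
from pathlib import Path
from typing import List, Optional, Tuple

from .seqformats import (
    SeqFormat,
    SequenceRecord,
    parse_records,
    revcomp,
)

__all__ = ["revcomp", "mock_align", "main"]


def _load_reference(path) -> List[Tuple[str, str]]:
    with open(path, "rb") as fh:
        return [(rec.read_id, rec.bases.upper()) for rec in parse_records(fh, SeqFormat.FASTA)]


def _search(refs: List[Tuple[str, str]], bases: str) -> Optional[Tuple[str, int, bool]]:
    """(reference name, 1-based position, reverse?) of the leftmost hit."""
    query = bases.upper()
    for name, seq in refs:
        pos = seq.find(query)
        if pos >= 0:
            return name, pos + 1, False
    rc = revcomp(query)
    for name, seq in refs:
        pos = seq.find(rc)
        if pos >= 0:
            return name, pos + 1, True
    return None


def _strip_pair_suffix(read_id: str) -> str:
    if len(read_id) > 2 and read_id[-2] == "/" and read_id[-1] in "12":
        return read_id[:-2]
    return read_id


def _sam_header(refs: List[Tuple[str, str]]) -> str:
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for name, seq in refs:
        lines.append(f"@SQ\tSN:{name}\tLN:{len(seq)}")
    return "".join(line + "\n" for line in lines)


def _oriented(rec: SequenceRecord, reverse: bool) -> Tuple[str, str]:
    # SAM stores the read in forward-genome orientation for reverse hits.
    seq = revcomp(rec.bases) if reverse else rec.bases
    if rec.qualities is None:
        qual = "*"
    else:
        qual = rec.qualities[::-1] if reverse else rec.qualities
    return seq, qual


def _single_line(rec: SequenceRecord, hit) -> str:
    if hit is None:
        return "\t".join([
            rec.read_id, "4", "*", "0", "0", "*", "*", "0", "0",
            rec.bases, rec.qualities or "*",
        ]) + "\n"
    name, pos, reverse = hit
    seq, qual = _oriented(rec, reverse)
    flag = 16 if reverse else 0
    return "\t".join([
        rec.read_id, str(flag), name, str(pos), "60", f"{len(rec.bases)}M",
        "*", "0", "0", seq, qual, "NM:i:0", "NH:i:1",
    ]) + "\n"


def _pair_lines(r1: SequenceRecord, r2: SequenceRecord, hit1, hit2) -> str:
    qname = _strip_pair_suffix(r1.read_id)
    out = []
    for rec, hit, mate_hit, first in ((r1, hit1, hit2, True), (r2, hit2, hit1, False)):
        flag = 0x1 | (0x40 if first else 0x80)
        if hit is None:
            flag |= 0x4
        elif hit[2]:
            flag |= 0x10
        if mate_hit is None:
            flag |= 0x8
        elif mate_hit[2]:
            flag |= 0x20
        if hit is not None and mate_hit is not None:
            flag |= 0x2
        if hit is None:
            rname, pos, mapq, cigar = "*", 0, 0, "*"
            seq, qual = rec.bases, rec.qualities or "*"
        else:
            rname, pos, reverse = hit
            mapq, cigar = 60, f"{len(rec.bases)}M"
            seq, qual = _oriented(rec, reverse)
        if mate_hit is None:
            rnext, pnext = "*", 0
        else:
            rnext = "=" if hit is not None and mate_hit[0] == hit[0] else mate_hit[0]
            pnext = mate_hit[1]
        tlen = 0
        if hit is not None and mate_hit is not None and mate_hit[0] == hit[0]:
            self_pos, mate_pos = hit[1], mate_hit[1]
            self_len, mate_len = len(rec.bases), 0
            mate_len = len((r2 if first else r1).bases)
            left = min(self_pos, mate_pos)
            right = max(self_pos + self_len, mate_pos + mate_len)
            span = right - left
            tlen = span if self_pos <= mate_pos else -span
        fields = [qname, str(flag), rname, str(pos), str(mapq), cigar,
                  rnext, str(pnext), str(tlen), seq, qual]
        if hit is not None:
            fields += ["NM:i:0", "NH:i:1"]
        out.append("\t".join(fields) + "\n")
    return "".join(out)


def _sniff_stream(path) -> Tuple[io.BufferedReader, SeqFormat]:
    fh = open(path, "rb")
    first = fh.peek(1)[:1]
    fmt = SeqFormat.FASTA if first == b">" else SeqFormat.FASTQ
    return fh, fmt


def mock_align(
    reference: Path,
    in1: Path,
    in2: Optional[Path] = None,
    out: Optional[io.TextIOBase] = None,
) -> None:
    """Align reads from *in1* (and *in2* in paired mode), writing SAM to *out*."""
    refs = _load_reference(reference)
    if out is None:
        out = sys.stdout
    out.write(_sam_header(refs))
    if in2 is None:
        fh, fmt = _sniff_stream(in1)
        with fh:
            for rec in parse_records(fh, fmt):
                out.write(_single_line(rec, _search(refs, rec.bases)))
    else:
        # Read the two inputs alternately, one record at a time, so that
        # feeders into two FIFOs progress roughly in lockstep.
        fh1, fmt1 = _sniff_stream(in1)
        fh2, fmt2 = _sniff_stream(in2)
        with fh1, fh2:
            it1 = parse_records(fh1, fmt1)
            it2 = parse_records(fh2, fmt2)
            for r1 in it1:
                r2 = next(it2, None)
                if r2 is None:
                    raise SystemExit("mock-aligner: input2 exhausted before input1")
                out.write(_pair_lines(r1, r2, _search(refs, r1.bases),
                                      _search(refs, r2.bases)))
            if next(it2, None) is not None:
                raise SystemExit("mock-aligner: input1 exhausted before input2")
    out.flush()


def main(argv: Optional[List[str]] = None) -> int:
    parser = argparse.ArgumentParser(prog="splitalign-mock-aligner",
                                     description=__doc__.splitlines()[0])
    parser.add_argument("--ref", required=True, type=Path)
    parser.add_argument("--in", dest="in1", required=True, type=Path)
    parser.add_argument("--in2", type=Path, default=None)
    parser.add_argument("--out", type=Path, default=None)
    parser.add_argument("--threads", type=int, default=1,
                        help="accepted for interface parity; alignment is exact-match")
    args = parser.parse_args(argv)
    if args.out is not None:
        with open(args.out, "w") as sink:
            mock_align(args.ref, args.in1, args.in2, sink)
    else:
        mock_align(args.ref, args.in1, args.in2, sys.stdout)
    return 0


if __name__ == "__main__":
    sys.exit(main())
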