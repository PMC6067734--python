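"""Deterministic synthetic references, read sets and adversarial files.

Everything here is reproducible byte-for-byte from an integer seed
(``random.Random`` over integer-only draws; gzip written with ``mtime=0``),
so the same spec always produces the same files on any platform.

Reads are sampled as exact substrings of the reference (either strand), so
the exact-match mock aligner maps every "mappable" read; an
``unmappable_fraction`` of reads is replaced by random sequence verified at
generation time to be absent from both strands, making downstream unmapped
counts and alignment rates analytically exact.  Qualities are the constant
'I' (Phred+33 score 40), which keeps the average-quality statistic exact as
well.  A sidecar tab-separated manifest records the ground truth (true
position, strand, mappability) per read.

The adversarial FASTQ generator stresses record-boundary synchronization:
every quality string *starts* with '@' or '+' characters and read lengths
are heterogeneous, so naive '@'-scanning misidentifies record starts.
"""

from __future__ import annotations

import bz2
import gzip
import random
from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple, Union

from .seqformats import CodecKind, SeqFormat, revcomp

__all__ = ["FixtureSpec", "generate_reference", "generate_reads",
           "generate_adversarial_fastq"]

_BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``read_length`` may be a single length or an inclusive ``(min, max)``
    range.  ``inner_distance`` is the gap between the two ends of a pair on
    the fragment.  ``asymmetric_layout`` pads the reverse file's record
    descriptions with seeded random-length filler so the two files of a pair
    have different byte layouts (exercising ordinal-based pairing).
    """

    seed: int = 1
    reference_length: int = 5000
    n_reads: int = 500
    read_length: Union[int, Tuple[int, int]] = 70
    paired: bool = False
    inner_distance: int = 60
    unmappable_fraction: float = 0.0
    fmt: SeqFormat = SeqFormat.FASTQ
    codec: CodecKind = CodecKind.PLAIN
    asymmetric_layout: bool = False


def _rng(spec_seed: int, salt: int) -> random.Random:
    return random.Random((spec_seed * 1_000_003 + salt) % (2**31 - 1))


def _random_bases(rng: random.Random, n: int) -> str:
    return "".join(_BASES[rng.randrange(4)] for _ in range(n))


def _write(path: Path, payload: bytes, codec: CodecKind) -> Path:
    if codec is CodecKind.GZIP:
        payload = gzip.compress(payload, mtime=0)
    elif codec is CodecKind.BZIP2:
        payload = bz2.compress(payload)
    path.write_bytes(payload)
    return path


def generate_reference(spec: FixtureSpec, out_dir: Union[str, Path]) -> Path:
    """Write a single-sequence FASTA reference named ``chrT``."""
    if spec.reference_length < 1:
        raise ValueError("reference_length must be >= 1")
    rng = _rng(spec.seed, 17)
    seq = _random_bases(rng, spec.reference_length)
    lines = [">chrT"]
    for i in range(0, len(seq), 60):
        lines.append(seq[i:i + 60])
    path = Path(out_dir) / f"ref-seed{spec.seed}.fasta"
    path.write_bytes("".join(line + "\n" for line in lines).encode())
    return path


def _read_len(spec: FixtureSpec, rng: random.Random) -> int:
    if isinstance(spec.read_length, tuple):
        lo, hi = spec.read_length
        return rng.randint(lo, hi)
    return spec.read_length


def _load_reference_seq(reference: Path) -> str:
    chunks = []
    with open(reference) as fh:
        for line in fh:
            if not line.startswith(">"):
                chunks.append(line.strip())
    return "".join(chunks)


def _unmappable_seq(rng: random.Random, length: int, ref: str, rc_ref: str) -> str:
    while True:
        seq = _random_bases(rng, length)
        if seq not in ref and seq not in rc_ref:
            return seq


def _format_record(fmt: SeqFormat, read_id: str, description: str, bases: str) -> str:
    header = f"{read_id} {description}" if description else read_id
    if fmt is SeqFormat.FASTQ:
        return f"@{header}\n{bases}\n+\n{'I' * len(bases)}\n"
    return f">{header}\n{bases}\n"


def generate_reads(
    spec: FixtureSpec, reference: Union[str, Path], out_dir: Union[str, Path]
) -> List[Path]:
    """Sample a read set from *reference*; returns 1 (single) or 2 (paired)
    file paths.  A ground-truth manifest is written next to the first file
    with suffix ``.manifest.tsv``."""
    reference = Path(reference)
    out_dir = Path(out_dir)
    ref = _load_reference_seq(reference)
    rc_ref = revcomp(ref)
    rng = _rng(spec.seed, 29)

    n_slots = spec.n_reads * (2 if spec.paired else 1)
    n_unmappable = round(spec.unmappable_fraction * n_slots)
    unmappable_slots = set(rng.sample(range(n_slots), n_unmappable))

    file1: List[str] = []
    file2: List[str] = []
    manifest = ["id\tref\tpos\tstrand\tmappable"]

    for i in range(spec.n_reads):
        length = _read_len(spec, rng)
        if spec.paired:
            frag = 2 * length + spec.inner_distance
            if frag > len(ref):
                raise ValueError(
                    f"fragment length {frag} exceeds reference length {len(ref)}"
                )
            p = rng.randrange(len(ref) - frag + 1)
            fwd = ref[p:p + length]
            rev = revcomp(ref[p + frag - length:p + frag])
            stem = f"pair{i:06d}"
            ends = [(fwd, p + 1, "+"), (rev, p + frag - length + 1, "-")]
            for end_idx, (bases, pos, strand) in enumerate(ends):
                slot = 2 * i + end_idx
                mappable = slot not in unmappable_slots
                if not mappable:
                    bases = _unmappable_seq(rng, length, ref, rc_ref)
                    pos, strand = 0, "."
                read_id = f"{stem}/{end_idx + 1}"
                if end_idx == 0:
                    desc = f"L{i}"
                    file1.append(_format_record(spec.fmt, read_id, desc, bases))
                else:
                    desc = f"R{i}"
                    if spec.asymmetric_layout:
                        desc += " " + "x" * rng.randint(0, 30)
                    file2.append(_format_record(spec.fmt, read_id, desc, bases))
                manifest.append(
                    f"{read_id}\tchrT\t{pos}\t{strand}\t{int(mappable)}"
                )
        else:
            p = rng.randrange(len(ref) - length + 1)
            strand = "+" if rng.randrange(2) == 0 else "-"
            bases = ref[p:p + length] if strand == "+" else revcomp(ref[p:p + length])
            mappable = i not in unmappable_slots
            if not mappable:
                bases = _unmappable_seq(rng, length, ref, rc_ref)
                p, strand = -1, "."
            read_id = f"read{i:06d}"
            file1.append(_format_record(spec.fmt, read_id, "", bases))
            manifest.append(f"{read_id}\tchrT\t{p + 1}\t{strand}\t{int(mappable)}")

    ext = "fastq" if spec.fmt is SeqFormat.FASTQ else "fasta"
    suffix = {CodecKind.PLAIN: "", CodecKind.GZIP: ".gz", CodecKind.BZIP2: ".bz2"}[spec.codec]
    stem = f"reads-seed{spec.seed}"
    paths = []
    if spec.paired:
        paths.append(_write(out_dir / f"{stem}_1.{ext}{suffix}",
                            "".join(file1).encode(), spec.codec))
        paths.append(_write(out_dir / f"{stem}_2.{ext}{suffix}",
                            "".join(file2).encode(), spec.codec))
    else:
        paths.append(_write(out_dir / f"{stem}.{ext}{suffix}",
                            "".join(file1).encode(), spec.codec))
    manifest_path = Path(str(paths[0]) + ".manifest.tsv")
    manifest_path.write_text("".join(line + "\n" for line in manifest))
    return paths


def generate_adversarial_fastq(
    seed: int, n_reads: int, out_dir: Union[str, Path]
) -> Path:
    """FASTQ whose quality strings begin with '@' or '+' and whose read
    lengths vary, defeating naive record-start scanning."""
    if n_reads < 2:
        raise ValueError("n_reads must be >= 2")
    rng = _rng(seed, 43)
    records = []
    for i in range(n_reads):
        length = rng.randint(5, 40)
        bases = _random_bases(rng, length)
        sigil = "@" if rng.randrange(2) == 0 else "+"
        k = rng.randint(1, length)
        qual = sigil * k + "I" * (length - k)
        records.append(f"@adv{i:05d}\n{bases}\n+\n{qual}\n")
    path = Path(out_dir) / f"adversarial-seed{seed}.fastq"
    path.write_bytes("".join(records).encode())
    return path
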