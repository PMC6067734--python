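"""Shared fixtures and independent oracles.

The oracles here are deliberately simple and separate from the library
paths they check: whole-file parses collect true record-header offsets by
re-reading every serialized record's byte length, and Biopython re-parses
files the hand-written parser produced.
"""

from __future__ import annotations

import io
from pathlib import Path

import pytest

from splitalign.aligner_adapter import builtin_config_path, load_aligner_spec
from splitalign.fixtures import FixtureSpec, generate_reads, generate_reference
from splitalign.seqformats import SeqFormat, parse_records, serialize_record


def true_record_offsets(path: Path, fmt: SeqFormat) -> list[int]:
    """Brute-force oracle: byte offsets of every record header, obtained by
    a whole-file parse (not by scanning for sigil bytes)."""
    with open(path, "rb") as fh:
        from splitalign.seqformats import parse_with_offsets

        return [off for off, _ in parse_with_offsets(fh, fmt)]


def whole_file_ids(path: Path, fmt: SeqFormat) -> list[str]:
    with open(path, "rb") as fh:
        return [rec.read_id for rec in parse_records(fh, fmt)]


@pytest.fixture(scope="session")
def mock_spec():
    return load_aligner_spec(builtin_config_path("mock"))


@pytest.fixture(scope="session")
def toy_dataset(tmp_path_factory):
    """Reference + 100 single-end FASTQ reads, 10% unmappable."""
    tmp = tmp_path_factory.mktemp("toy")
    spec = FixtureSpec(seed=11, n_reads=100, reference_length=3000,
                       read_length=50, unmappable_fraction=0.1)
    ref = generate_reference(spec, tmp)
    reads = generate_reads(spec, ref, tmp)[0]
    return {"spec": spec, "reference": ref, "reads": reads, "dir": tmp}


@pytest.fixture(scope="session")
def paired_dataset(tmp_path_factory):
    """Reference + 80 read pairs with asymmetric per-file byte layouts."""
    tmp = tmp_path_factory.mktemp("paired")
    spec = FixtureSpec(seed=13, n_reads=80, reference_length=4000,
                       read_length=45, paired=True, asymmetric_layout=True)
    ref = generate_reference(spec, tmp)
    r1, r2 = generate_reads(spec, ref, tmp)
    return {"spec": spec, "reference": ref, "reads1": r1, "reads2": r2, "dir": tmp}
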