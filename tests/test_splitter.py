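"""Split planning, record-boundary synchronization and paired composites."""

import gzip
import random

import pytest

from splitalign.fixtures import FixtureSpec, generate_adversarial_fastq, generate_reads, generate_reference
from splitalign.seqformats import CodecKind, SeqFormat, parse_records
from splitalign.splitter import (
    PairingError,
    compute_split_size,
    pair_splits,
    pair_stem,
    plan_splits,
    plan_synced_splits,
    read_composite,
    read_split,
    sync_to_record_start,
    manifest_lines,
)

from conftest import true_record_offsets, whole_file_ids


class TestComputeSplitSize:
    @pytest.mark.parametrize(
        "total,tasks,expected",
        [(1000, 4, 250), (1001, 4, 251), (10, 32, 1), (1, 1, 1), (7, 3, 3)],
    )
    def test_ceiling_division(self, total, tasks, expected):
        assert compute_split_size(total, tasks) == expected

    @pytest.mark.parametrize("total,tasks", [(0, 4), (100, 0), (-1, 1)])
    def test_rejects_non_positive(self, total, tasks):
        with pytest.raises(ValueError):
            compute_split_size(total, tasks)


class TestPlanSplits:
    def test_plain_consecutive_ranges(self, tmp_path):
        f = tmp_path / "f"
        f.write_bytes(b"x" * 1000)
        splits = plan_splits(f, CodecKind.PLAIN, 300)
        assert [(s.start, s.end) for s in splits] == [
            (0, 300), (300, 600), (600, 900), (900, 1000)
        ]
        assert [s.index for s in splits] == [0, 1, 2, 3]

    def test_compressed_single_split(self, tmp_path):
        f = tmp_path / "f"
        f.write_bytes(b"x" * 1000)
        splits = plan_splits(f, CodecKind.GZIP, 300)
        assert [(s.start, s.end) for s in splits] == [(0, 1000)]

    def test_file_smaller_than_split(self, tmp_path):
        f = tmp_path / "f"
        f.write_bytes(b"x" * 299)
        assert [(s.start, s.end) for s in plan_splits(f, CodecKind.PLAIN, 300)] == [(0, 299)]

    def test_empty_file_rejected(self, tmp_path):
        f = tmp_path / "f"
        f.touch()
        with pytest.raises(ValueError, match="empty"):
            plan_splits(f, CodecKind.PLAIN, 300)


class TestSyncToRecordStart:
    def test_offset_zero_is_identity(self, tmp_path):
        f = tmp_path / "f.fastq"
        f.write_bytes(b"@a\nAC\n+\nII\n@b\nGG\n+\nII\n")
        assert sync_to_record_start(f, 0, SeqFormat.FASTQ) == 0

    def test_mid_record_syncs_to_next(self, tmp_path):
        f = tmp_path / "f.fastq"
        f.write_bytes(b"@a\nAC\n+\nII\n@b\nGG\n+\nII\n")
        offsets = true_record_offsets(f, SeqFormat.FASTQ)
        assert offsets == [0, 11]
        assert sync_to_record_start(f, 5, SeqFormat.FASTQ) == 11

    def test_at_quality_sigil_skips_quality_line(self, tmp_path):
        # quality line of record 1 is '@@@@': any offset inside record 1
        # must sync to record 2, never to the quality line
        payload = b"@a\nACGT\n+\n@@@@\n@b\nGGGG\n+\nIIII\n"
        f = tmp_path / "f.fastq"
        f.write_bytes(payload)
        offsets = true_record_offsets(f, SeqFormat.FASTQ)
        assert offsets == [0, 15]
        for off in range(1, 15):
            assert sync_to_record_start(f, off, SeqFormat.FASTQ) == 15

    def test_fasta_header_scan(self, tmp_path):
        f = tmp_path / "f.fasta"
        f.write_bytes(b">a\nAC\nGT\n>b\nCC\n")
        assert sync_to_record_start(f, 1, SeqFormat.FASTA) == 9
        assert sync_to_record_start(f, 9, SeqFormat.FASTA) == 9

    def test_no_record_after_offset_returns_size(self, tmp_path):
        f = tmp_path / "f.fastq"
        f.write_bytes(b"@a\nAC\n+\nII\n")
        size = 11
        assert sync_to_record_start(f, 4, SeqFormat.FASTQ) == size

    def test_exhaustive_oracle_agreement_adversarial(self, tmp_path):
        """Every byte offset of a boundary-adversarial file syncs to exactly
        the first true record start at or after it."""
        path = generate_adversarial_fastq(seed=5, n_reads=40, out_dir=tmp_path)
        offsets = true_record_offsets(path, SeqFormat.FASTQ)
        size = path.stat().st_size
        for off in range(size + 1):
            expected = next((o for o in offsets if o >= off), size)
            assert sync_to_record_start(path, off, SeqFormat.FASTQ) == expected


class TestReadSplit:
    def _dataset(self, tmp_path, n_reads=30, fmt=SeqFormat.FASTQ):
        spec = FixtureSpec(seed=7, n_reads=n_reads, reference_length=1500,
                           read_length=(20, 45), fmt=fmt)
        ref = generate_reference(spec, tmp_path)
        return generate_reads(spec, ref, tmp_path)[0]

    @pytest.mark.parametrize("fmt", [SeqFormat.FASTQ, SeqFormat.FASTA])
    def test_union_of_splits_equals_whole_parse(self, tmp_path, fmt):
        path = self._dataset(tmp_path, fmt=fmt)
        expected = whole_file_ids(path, fmt)
        size = path.stat().st_size
        for split_size in [1, 17, 64, 301, size // 2, size]:
            splits = plan_synced_splits(path, fmt, split_size)
            got = [rec.read_id for s in splits for _, rec in read_split(s, fmt)]
            assert got == expected, f"split_size={split_size}"

    def test_keys_are_per_split_ordinals(self, tmp_path):
        path = self._dataset(tmp_path)
        splits = plan_synced_splits(path, SeqFormat.FASTQ, 400)
        for s in splits:
            keys = [k for k, _ in read_split(s, SeqFormat.FASTQ)]
            assert keys == list(range(s.record_count))

    def test_zero_record_split_is_empty(self, tmp_path):
        path = self._dataset(tmp_path)
        # split size 1 guarantees many splits own no record
        splits = plan_synced_splits(path, SeqFormat.FASTQ, 1)
        empty = [s for s in splits if s.record_count == 0]
        assert empty
        for s in empty[:5]:
            assert list(read_split(s, SeqFormat.FASTQ)) == []

    def test_record_counts_match_ownership(self, tmp_path):
        path = self._dataset(tmp_path)
        splits = plan_synced_splits(path, SeqFormat.FASTQ, 256)
        offsets = true_record_offsets(path, SeqFormat.FASTQ)
        for s in splits:
            owned = [o for o in offsets if s.first_record_offset <= o < s.base.end]
            assert s.record_count == len(owned)

    def test_manifest_lines_roundtrip_fields(self, tmp_path):
        path = self._dataset(tmp_path)
        splits = plan_synced_splits(path, SeqFormat.FASTQ, 512)
        lines = manifest_lines(splits)
        assert len(lines) == len(splits)
        fields = lines[0].split("\t")
        assert fields[0] == str(path) and int(fields[1]) == 0


def test_split_completeness_randomized(tmp_path):
    """For randomized (file, split size) pairs the concatenated split
    streams equal the whole-file parse (order and multiplicity)."""
    rng = random.Random(99)
    cases = 0
    for seed in range(6):
        spec = FixtureSpec(seed=200 + seed, n_reads=rng.randint(5, 120),
                           reference_length=1200, read_length=(15, 60))
        ref = generate_reference(spec, tmp_path)
        path = generate_reads(spec, ref, tmp_path)[0]
        expected = whole_file_ids(path, SeqFormat.FASTQ)
        size = path.stat().st_size
        for _ in range(6):
            split_size = rng.randint(1, size)
            splits = plan_synced_splits(path, SeqFormat.FASTQ, split_size)
            got = [r.read_id for s in splits for _, r in read_split(s, SeqFormat.FASTQ)]
            assert got == expected
            cases += 1
    assert cases == 36


class TestPairSplits:
    def _paired(self, tmp_path, n=50, asymmetric=True):
        spec = FixtureSpec(seed=21, n_reads=n, reference_length=3000,
                           read_length=(25, 40), paired=True,
                           asymmetric_layout=asymmetric)
        ref = generate_reference(spec, tmp_path)
        return generate_reads(spec, ref, tmp_path)

    def test_equal_counts_any_split_size(self, tmp_path):
        r1, r2 = self._paired(tmp_path)
        for split_size in [64, 333, 1000, r1.stat().st_size]:
            left = plan_synced_splits(r1, SeqFormat.FASTQ, split_size)
            right = plan_synced_splits(r2, SeqFormat.FASTQ, split_size)
            composites = pair_splits(left, right)
            assert sum(c.left.record_count for c in composites) == 50
            for c in composites:
                assert c.left.record_count == c.right.record_count

    def test_id_stems_match_pairwise(self, tmp_path):
        r1, r2 = self._paired(tmp_path)
        left = plan_synced_splits(r1, SeqFormat.FASTQ, 200)
        right = plan_synced_splits(r2, SeqFormat.FASTQ, 200)
        for comp in pair_splits(left, right):
            lids = [r for _, r in read_split(comp.left, SeqFormat.FASTQ)]
            rids = [r for _, r in read_split(comp.right, SeqFormat.FASTQ)]
            assert [pair_stem(r) for r in lids] == [pair_stem(r) for r in rids]

    def test_count_mismatch_reports_both_counts(self, tmp_path):
        r1, r2 = self._paired(tmp_path)
        with open(r1, "ab") as fh:
            fh.write(b"@extra/1\nACGT\n+\nIIII\n")
        left = plan_synced_splits(r1, SeqFormat.FASTQ, 400)
        right = plan_synced_splits(r2, SeqFormat.FASTQ, 400)
        with pytest.raises(PairingError, match="51.*50"):
            pair_splits(left, right)

    def test_verify_ids_flags_shuffled_file(self, tmp_path):
        r1, r2 = self._paired(tmp_path, n=10, asymmetric=False)
        # swap the first two records of the reverse file
        recs = list(parse_records(open(r2, "rb"), SeqFormat.FASTQ))
        from splitalign.seqformats import serialize_record
        recs[0], recs[1] = recs[1], recs[0]
        r2.write_bytes(b"".join(serialize_record(r) for r in recs))
        left = plan_synced_splits(r1, SeqFormat.FASTQ, 10_000)
        right = plan_synced_splits(r2, SeqFormat.FASTQ, 10_000)
        with pytest.raises(PairingError, match="stems differ"):
            pair_splits(left, right, verify_ids=True)

    def test_single_split_files_one_composite(self, tmp_path):
        r1, r2 = self._paired(tmp_path)
        left = plan_synced_splits(r1, SeqFormat.FASTQ, 10**9)
        right = plan_synced_splits(r2, SeqFormat.FASTQ, 10**9)
        (comp,) = pair_splits(left, right)
        assert comp.left.record_count == 50

    def test_compressed_side_collapses_to_one_composite(self, tmp_path):
        r1, r2 = self._paired(tmp_path)
        gz = tmp_path / "r2.fastq.gz"
        gz.write_bytes(gzip.compress(r2.read_bytes(), mtime=0))
        left = plan_synced_splits(r1, SeqFormat.FASTQ, 300)
        right = plan_synced_splits(gz, SeqFormat.FASTQ, 300, codec=CodecKind.GZIP)
        composites = pair_splits(left, right)
        assert len(composites) == 1
        assert composites[0].left.record_count == 50


class TestReadComposite:
    def test_key_splits_merged_value_exactly(self, tmp_path):
        spec = FixtureSpec(seed=31, n_reads=20, reference_length=2000,
                           read_length=(20, 35), paired=True, asymmetric_layout=True)
        ref = generate_reference(spec, tmp_path)
        r1, r2 = generate_reads(spec, ref, tmp_path)
        left = plan_synced_splits(r1, SeqFormat.FASTQ, 300)
        right = plan_synced_splits(r2, SeqFormat.FASTQ, 300)
        import io as _io

        from splitalign.seqformats import parse_fastq

        n_pairs = 0
        for comp in pair_splits(left, right):
            for key, merged in read_composite(comp):
                fwd, rev = merged[:key], merged[key:]
                (frec,) = list(parse_fastq(_io.BytesIO(fwd)))
                (rrec,) = list(parse_fastq(_io.BytesIO(rev)))
                assert pair_stem(frec) == pair_stem(rrec)
                assert frec.read_id.endswith("/1") and rrec.read_id.endswith("/2")
                n_pairs += 1
        assert n_pairs == 20
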