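"""Orchestration: task planning, the three run modes, and their invariants."""

import io
import sys

import pytest

from splitalign.engine import (
    EngineError,
    JoinError,
    ResourceError,
    RunConfig,
    plan_tasks,
    run,
    run_paired_mapside,
    run_paired_reduceside,
    run_single_end,
)
from splitalign.fixtures import FixtureSpec, generate_reads, generate_reference
from splitalign.mock_aligner import mock_align
from splitalign.samstats import merge_sam, sorted_body_lines
from splitalign.seqformats import SeqFormat


def _single_cfg(toy, out_dir, **kw):
    defaults = dict(
        mode="single", inputs=(toy["reads"],), index=toy["reference"],
        output_dir=out_dir, n_workers=2, timeout=120,
    )
    defaults.update(kw)
    return RunConfig(aligner=kw.pop("aligner"), **{k: v for k, v in defaults.items()
                                                   if k != "aligner"})


def _paired_cfg(ds, out_dir, strategy, mock_spec, **kw):
    defaults = dict(
        mode="paired", inputs=(ds["reads1"], ds["reads2"]), index=ds["reference"],
        aligner=mock_spec, output_dir=out_dir, join_strategy=strategy,
        n_workers=2, timeout=120,
    )
    defaults.update(kw)
    return RunConfig(**defaults)


def _oracle_sam(ds, out_path, paired=False):
    """Whole-file mock alignment, bypassing the engine entirely."""
    with open(out_path, "w") as sink:
        if paired:
            mock_align(ds["reference"], ds["reads1"], ds["reads2"], sink)
        else:
            mock_align(ds["reference"], ds["reads"], out=sink)
    return out_path


class TestPlanTasks:
    def test_auto_split_matches_worker_count(self, toy_dataset, mock_spec, tmp_path):
        cfg = _single_cfg(toy_dataset, tmp_path, aligner=mock_spec, n_workers=4)
        splits = plan_tasks(cfg)
        assert len(splits) == 4
        assert sum(s.record_count for s in splits) == 100

    def test_paired_auto_yields_composites(self, paired_dataset, mock_spec, tmp_path):
        cfg = _paired_cfg(paired_dataset, tmp_path, "map_side", mock_spec)
        composites = plan_tasks(cfg)
        assert len(composites) == 2
        assert all(c.left.record_count == c.right.record_count for c in composites)

    def test_memory_oversubscription_fails_before_launch(self, toy_dataset, mock_spec, tmp_path):
        cfg = _single_cfg(toy_dataset, tmp_path, aligner=mock_spec,
                          memory_per_aligner=1 << 40, n_workers=2)
        with pytest.raises(ResourceError, match="exceeds detected system memory"):
            plan_tasks(cfg)
        assert not any(tmp_path.iterdir())  # nothing was launched or written


class TestSingleEnd:
    def test_shards_cover_all_reads(self, toy_dataset, mock_spec, tmp_path):
        cfg = _single_cfg(toy_dataset, tmp_path / "out", aligner=mock_spec)
        shards = run_single_end(cfg)
        assert len(shards.shard_paths) == 2
        merged = merge_sam(shards.shard_paths, tmp_path / "merged.sam")
        body = sorted_body_lines(merged)
        assert len(body) == 100  # read conservation: one record per read
        assert shards.grouping_ops == 0  # map-only: no grouping anywhere

    def test_matches_whole_file_oracle(self, toy_dataset, mock_spec, tmp_path):
        cfg = _single_cfg(toy_dataset, tmp_path / "out", aligner=mock_spec)
        shards = run_single_end(cfg)
        merged = merge_sam(shards.shard_paths, tmp_path / "merged.sam")
        oracle = _oracle_sam(toy_dataset, tmp_path / "oracle.sam")
        assert sorted_body_lines(merged) == sorted_body_lines(oracle)

    def test_zero_record_split_yields_header_only_shard(self, mock_spec, tmp_path):
        spec = FixtureSpec(seed=77, n_reads=2, reference_length=500, read_length=30)
        ref = generate_reference(spec, tmp_path)
        reads = generate_reads(spec, ref, tmp_path)[0]
        ds = {"reads": reads, "reference": ref}
        # tiny splits: most own zero records but still produce valid shards
        cfg = _single_cfg(ds, tmp_path / "out", aligner=mock_spec,
                          n_workers=2, split_size=11)
        shards = run_single_end(cfg)
        empty = [t for t in shards.task_manifest if t.record_count == 0]
        assert empty
        for task in empty:
            lines = task.shard.read_text().splitlines()
            assert lines and all(l.startswith("@") for l in lines)

    def test_failing_aligner_aborts_and_cleans_shards(self, toy_dataset, tmp_path):
        from splitalign.aligner_adapter import AlignerSpec
        bad = AlignerSpec(
            name="broken", executable=f"{sys.executable} -c 'import sys; sys.exit(3)'",
            single_end_template="{input1} {output}",
            paired_end_template="{input1} {input2} {output}",
        )
        cfg = _single_cfg(toy_dataset, tmp_path / "out", aligner=bad, n_workers=2)
        with pytest.raises(EngineError, match="task"):
            run_single_end(cfg)
        assert not list((tmp_path / "out").glob("part-*.sam"))


class TestPaired:
    def test_mapside_matches_materialized_oracle(self, paired_dataset, mock_spec, tmp_path):
        cfg = _paired_cfg(paired_dataset, tmp_path / "out", "map_side", mock_spec)
        shards = run_paired_mapside(cfg)
        assert shards.grouping_ops == 0
        merged = merge_sam(shards.shard_paths, tmp_path / "map.sam")
        oracle = _oracle_sam(paired_dataset, tmp_path / "oracle.sam", paired=True)
        assert sorted_body_lines(merged) == sorted_body_lines(oracle)
        assert len(sorted_body_lines(merged)) == 160  # 2 x 80 pairs

    def test_emitted_pairs_share_qname(self, paired_dataset, mock_spec, tmp_path):
        cfg = _paired_cfg(paired_dataset, tmp_path / "out", "map_side", mock_spec)
        shards = run_paired_mapside(cfg)
        merged = merge_sam(shards.shard_paths, tmp_path / "map.sam")
        from collections import Counter
        qnames = Counter(
            line.split("\t")[0] for line in sorted_body_lines(merged)
        )
        assert all(count == 2 for count in qnames.values())

    def test_reduceside_groups_and_matches_mapside(self, paired_dataset, mock_spec, tmp_path):
        map_cfg = _paired_cfg(paired_dataset, tmp_path / "m", "map_side", mock_spec)
        red_cfg = _paired_cfg(paired_dataset, tmp_path / "r", "reduce_side", mock_spec)
        map_shards = run_paired_mapside(map_cfg)
        red_shards = run_paired_reduceside(red_cfg)
        assert red_shards.grouping_ops == 80   # one group per pair
        a = merge_sam(map_shards.shard_paths, tmp_path / "map.sam")
        b = merge_sam(red_shards.shard_paths, tmp_path / "red.sam")
        assert sorted_body_lines(a) == sorted_body_lines(b)

    def test_reduceside_spill_path_equivalent(self, paired_dataset, mock_spec, tmp_path):
        """Forcing the shuffle spool to disk must not change the output."""
        mem_cfg = _paired_cfg(paired_dataset, tmp_path / "a", "reduce_side", mock_spec)
        disk_cfg = _paired_cfg(paired_dataset, tmp_path / "b", "reduce_side",
                               mock_spec, shuffle_memory_budget=64)
        a = merge_sam(run_paired_reduceside(mem_cfg).shard_paths, tmp_path / "a.sam")
        b = merge_sam(run_paired_reduceside(disk_cfg).shard_paths, tmp_path / "b.sam")
        assert sorted_body_lines(a) == sorted_body_lines(b)

    def test_forged_extra_record_raises_join_error(self, mock_spec, tmp_path):
        spec = FixtureSpec(seed=55, n_reads=20, reference_length=2000,
                           read_length=30, paired=True)
        ref = generate_reference(spec, tmp_path)
        r1, r2 = generate_reads(spec, ref, tmp_path)
        with open(r1, "ab") as fh:
            fh.write(b"@forged/1\nACGT\n+\nIIII\n")
        ds = {"reads1": r1, "reads2": r2, "reference": ref}
        cfg = _paired_cfg(ds, tmp_path / "out", "reduce_side", mock_spec)
        with pytest.raises((JoinError, EngineError, Exception)) as err:
            run_paired_reduceside(cfg)
        assert "21" in str(err.value) or "group" in str(err.value)


@pytest.mark.parametrize("mode,strategy", [
    ("single", None), ("paired", "map_side"), ("paired", "reduce_side"),
])
def test_worker_count_invariance(mode, strategy, toy_dataset, paired_dataset,
                                 mock_spec, tmp_path):
    """n_workers in {1, 2, 4} gives identical position-sorted merged SAM
    bodies in every mode (deterministic mock aligner)."""
    bodies = []
    for n in (1, 2, 4):
        out = tmp_path / f"{mode}-{strategy}-{n}"
        if mode == "single":
            cfg = _single_cfg(toy_dataset, out, aligner=mock_spec, n_workers=n)
        else:
            cfg = _paired_cfg(paired_dataset, out, strategy, mock_spec, n_workers=n)
        shards = run(cfg)
        assert shards.peak_workers <= n
        merged = merge_sam(shards.shard_paths, out / "merged.sam")
        bodies.append(sorted_body_lines(merged))
    assert bodies[0] == bodies[1] == bodies[2]


def test_compressed_inputs_match_plain_end_to_end(mock_spec, tmp_path):
    """gzip and bzip2 twins of a plain input produce identical output."""
    from splitalign.seqformats import CodecKind

    bodies = {}
    for codec in (CodecKind.PLAIN, CodecKind.GZIP, CodecKind.BZIP2):
        spec = FixtureSpec(seed=61, n_reads=40, reference_length=1500,
                           read_length=35, codec=codec, unmappable_fraction=0.1)
        d = tmp_path / codec.value
        d.mkdir()
        ref = generate_reference(spec, d)
        reads = generate_reads(spec, ref, d)[0]
        cfg = RunConfig(mode="single", inputs=(reads,), index=ref,
                        aligner=mock_spec, output_dir=d / "out", n_workers=2,
                        timeout=120)
        shards = run(cfg)
        merged = merge_sam(shards.shard_paths, d / "merged.sam")
        bodies[codec] = sorted_body_lines(merged)
    assert bodies[CodecKind.PLAIN] == bodies[CodecKind.GZIP] == bodies[CodecKind.BZIP2]
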