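"""Parallel alignment orchestration.

Three execution modes, all scatter-gather over byte-range splits with one
external aligner instance per task and two-level parallelism (``n_workers``
concurrent aligner processes, each using ``threads_per_worker`` aligner
threads):

* **single-end** — a map-only pipeline: each synced split is streamed into
  one FEED FIFO while the aligner's SAM is concurrently drained into the
  task's shard file.  No grouping or sorting of reads happens anywhere.
* **paired-end, map-side join** — the two ends are joined while reading:
  each composite split yields merged forward+reverse values that are cut at
  the key (the forward end's byte length) and streamed into two FEED FIFOs.
  Also map-only.
* **paired-end, reduce-side join** — the naive strategy kept for
  comparison: each file's splits are scanned independently, emitting
  ``((split_index, ordinal), file_tag, record)`` items; a group-by-key
  stage (the shuffle analog, spooled through per-reducer temporary files
  when a memory budget is exceeded) pairs the ends; each reducer then feeds
  one aligner.  The ordinal-aligned composite construction guarantees the
  j-th record of split i in one file pairs with the j-th record of split i
  in the other.

The run is fail-fast: the first task failure aborts the run, partial shards
are removed, and the task's diagnostics propagate.  A ``grouping_ops``
counter in the result records how many group-by-key operations executed —
zero in the two map-only modes.
"""

from __future__ import annotations

import os
import shutil
import struct
import tempfile
import threading
import uuid
from concurrent.futures import FIRST_EXCEPTION, ThreadPoolExecutor, wait
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

from .aligner_adapter import AlignerSpec, build_command
from .ipc import fifo_session, run_piped
from .seqformats import SeqFormat, detect_codec
from .splitter import (
    compute_split_size,
    pair_splits,
    plan_synced_splits,
    read_composite,
    read_split,
)

__all__ = [
    "RunConfig",
    "ShardSet",
    "TaskInfo",
    "EngineError",
    "ResourceError",
    "JoinError",
    "AUTO",
    "plan_tasks",
    "run",
    "run_single_end",
    "run_paired_mapside",
    "run_paired_reduceside",
]

AUTO = None  # sentinel for automatic split sizing


class EngineError(RuntimeError):
    pass


class ResourceError(EngineError):
    pass


class JoinError(EngineError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Everything one alignment run needs.

    ``split_size=AUTO`` sizes splits so that the number of tasks equals
    ``n_workers`` (ceil of input bytes over workers).  ``memory_per_aligner``
    (bytes), when given, caps ``n_workers`` against detected system memory
    before anything is launched.
    """

    mode: str                     # "single" | "paired"
    inputs: Tuple[Path, ...]
    index: Path
    aligner: AlignerSpec
    output_dir: Path
    fmt: SeqFormat = SeqFormat.FASTQ
    join_strategy: str = "map_side"   # paired only: "map_side" | "reduce_side"
    n_workers: int = 1
    threads_per_worker: int = 1
    split_size: Optional[int] = AUTO
    merge_output: bool = False
    seed: int = 0
    memory_per_aligner: Optional[int] = None
    shuffle_memory_budget: int = 256 << 20
    timeout: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("single", "paired"):
            raise ValueError(f"mode must be 'single' or 'paired', got {self.mode!r}")
        expected = 1 if self.mode == "single" else 2
        if len(self.inputs) != expected:
            raise ValueError(f"{self.mode} mode needs {expected} input file(s)")
        if self.join_strategy not in ("map_side", "reduce_side"):
            raise ValueError(f"unknown join_strategy {self.join_strategy!r}")
        if self.n_workers < 1 or self.threads_per_worker < 1:
            raise ValueError("n_workers and threads_per_worker must be >= 1")


@dataclass(frozen=True)
class TaskInfo:
    split_index: int
    record_count: int
    exit_status: int
    shard: Path


@dataclass(frozen=True)
class ShardSet:
    """Result of a run: ordered shard paths plus per-task accounting."""

    shard_paths: Tuple[Path, ...]
    task_manifest: Tuple[TaskInfo, ...]
    grouping_ops: int
    peak_workers: int


def _detected_memory() -> int:
    return os.sysconf("SC_PAGE_SIZE") * os.sysconf("SC_PHYS_PAGES")


def _check_memory(config: RunConfig) -> None:
    if config.memory_per_aligner is None:
        return
    need = config.memory_per_aligner * config.n_workers
    have = _detected_memory()
    if need > have:
        raise ResourceError(
            f"{config.n_workers} workers x {config.memory_per_aligner} bytes "
            f"= {need} bytes exceeds detected system memory ({have} bytes)"
        )


def _resolve_split_size(config: RunConfig) -> int:
    if config.split_size is not AUTO:
        return config.split_size
    total = os.path.getsize(config.inputs[0])
    return compute_split_size(total, config.n_workers)


def plan_tasks(config: RunConfig):
    """Plan the (composite) splits this run will execute, one task each.

    Raises :class:`ResourceError` before launching anything when the memory
    arithmetic over-subscribes the machine.
    """
    for path in config.inputs:
        if not Path(path).exists():
            raise FileNotFoundError(path)
    _check_memory(config)
    split_size = _resolve_split_size(config)
    left = plan_synced_splits(config.inputs[0], config.fmt, split_size)
    if config.mode == "single":
        return left
    right_codec = detect_codec(config.inputs[1])
    right = plan_synced_splits(config.inputs[1], config.fmt, split_size,
                               codec=right_codec)
    return pair_splits(left, right)


class _Gauge:
    """Tracks concurrent aligner instances; peak proves the worker cap."""

    def __init__(self) -> None:
        self._lock = threading.Lock()
        self._active = 0
        self.peak = 0

    def __enter__(self) -> "_Gauge":
        with self._lock:
            self._active += 1
            self.peak = max(self.peak, self._active)
        return self

    def __exit__(self, *exc) -> None:
        with self._lock:
            self._active -= 1


def _shard_path(output_dir: Path, index: int) -> Path:
    return output_dir / f"part-{index:05d}.sam"


def _run_aligner_task(
    config: RunConfig,
    task_index: int,
    n_inputs: int,
    feeder_streams,
    record_count: int,
    gauge: _Gauge,
) -> TaskInfo:
    output_dir = Path(config.output_dir)
    shard = _shard_path(output_dir, task_index)
    tmp_shard = shard.with_suffix(".sam.tmp")
    fifo_dir = output_dir / f".fifo-{task_index:05d}-{uuid.uuid4().hex[:8]}"
    log_dir = output_dir / "logs"
    log_dir.mkdir(exist_ok=True)
    fifo_dir.mkdir()
    try:
        with fifo_session(fifo_dir, n_inputs) as endpoints:
            feeds, drain_ep = endpoints[:-1], endpoints[-1]
            mode = "single" if n_inputs == 1 else "paired"
            if config.aligner.stdout_mode:
                cmd = build_command(
                    config.aligner, mode, config.fmt, config.index,
                    [ep.path for ep in feeds], None, config.threads_per_worker,
                )
                drain_arg = None
            else:
                cmd = build_command(
                    config.aligner, mode, config.fmt, config.index,
                    [ep.path for ep in feeds], drain_ep.path,
                    config.threads_per_worker,
                )
                drain_arg = drain_ep
            with open(tmp_shard, "wb") as sink, gauge:
                report = run_piped(
                    cmd,
                    feeders=list(zip(feeds, feeder_streams)),
                    drain=(drain_arg, sink),
                    timeout=config.timeout,
                    stderr_path=log_dir / f"task-{task_index:05d}.stderr.log",
                )
        os.replace(tmp_shard, shard)
        return TaskInfo(split_index=task_index, record_count=record_count,
                        exit_status=report.child_exit_code, shard=shard)
    except BaseException:
        tmp_shard.unlink(missing_ok=True)
        shard.unlink(missing_ok=True)
        raise
    finally:
        shutil.rmtree(fifo_dir, ignore_errors=True)


def _execute(config: RunConfig, task_args: Sequence[tuple], grouping_ops: int) -> ShardSet:
    Path(config.output_dir).mkdir(parents=True, exist_ok=True)
    gauge = _Gauge()
    results: Dict[int, TaskInfo] = {}
    with ThreadPoolExecutor(max_workers=config.n_workers) as pool:
        futures = {
            pool.submit(_run_aligner_task, config, idx, n_in, streams, count, gauge): idx
            for idx, n_in, streams, count in task_args
        }
        done, pending = wait(futures, return_when=FIRST_EXCEPTION)
        first_error = None
        for fut in done:
            exc = fut.exception()
            if exc is not None and first_error is None:
                first_error = (futures[fut], exc)
        if first_error is not None:
            for fut in pending:
                fut.cancel()
            done2, _ = wait([f for f in futures if not f.cancelled()])
            for info in (f.result() for f in done2 if f.exception() is None):
                info.shard.unlink(missing_ok=True)
            idx, exc = first_error
            raise EngineError(f"task {idx} failed: {exc}") from exc
        for fut in done:
            info = fut.result()
            results[info.split_index] = info
    manifest = tuple(results[i] for i in sorted(results))
    return ShardSet(
        shard_paths=tuple(info.shard for info in manifest),
        task_manifest=manifest,
        grouping_ops=grouping_ops,
        peak_workers=gauge.peak,
    )


def run_single_end(config: RunConfig) -> ShardSet:
    """Map-only single-end run: one aligner per synced split."""
    if config.mode != "single":
        raise ValueError("run_single_end requires mode='single'")
    splits = plan_tasks(config)
    task_args = []
    for split in splits:
        stream = (rec for _key, rec in read_split(split, config.fmt))
        task_args.append((split.base.index, 1, [stream], split.record_count))
    return _execute(config, task_args, grouping_ops=0)


class _PairFeed:
    """Split a (key, merged) composite stream into two coupled byte streams.

    Two consumer threads pull the forward and reverse sides; a shared lock
    advances the underlying iterator only when a side's buffer is empty, so
    buffering is bounded by the consumers' skew (about one FIFO buffer when
    the child reads its two inputs in lockstep).
    """

    def __init__(self, pairs: Iterator[Tuple[int, bytes]]):
        self._it = pairs
        self._lock = threading.Lock()
        self._buf: Tuple[List[bytes], List[bytes]] = ([], [])
        self._done = False

    def side(self, which: int) -> Iterator[bytes]:
        buf = self._buf[which]
        while True:
            with self._lock:
                if buf:
                    yield buf.pop(0)
                    continue
                if self._done:
                    return
                try:
                    key, merged = next(self._it)
                except StopIteration:
                    self._done = True
                    return
                self._buf[0].append(merged[:key])
                self._buf[1].append(merged[key:])


def run_paired_mapside(config: RunConfig) -> ShardSet:
    """Map-only paired run over composite splits (join while reading)."""
    if config.mode != "paired" or config.join_strategy != "map_side":
        raise ValueError("run_paired_mapside requires mode='paired', join_strategy='map_side'")
    composites = plan_tasks(config)
    task_args = []
    for comp in composites:
        feed = _PairFeed(read_composite(comp, config.fmt))
        task_args.append(
            (comp.index, 2, [feed.side(0), feed.side(1)], comp.left.record_count)
        )
    return _execute(config, task_args, grouping_ops=0)


_SPOOL_HEADER = struct.Struct("<IIBI")  # split_index, ordinal, tag, payload length


class _ReducerSpool:
    """Shuffle-analog buffer for one reducer: in memory up to a budget,
    spilled to a temporary file beyond it."""

    def __init__(self, budget: int, tmp_dir: Path):
        self._budget = budget
        self._tmp_dir = tmp_dir
        self._items: List[Tuple[int, int, int, bytes]] = []
        self._bytes = 0
        self._spill = None

    def add(self, split_index: int, ordinal: int, tag: int, payload: bytes) -> None:
        if self._spill is None and self._bytes + len(payload) > self._budget:
            self._spill = tempfile.NamedTemporaryFile(
                dir=self._tmp_dir, prefix="shuffle-", delete=False
            )
            for item in self._items:
                self._write(self._spill, *item)
            self._items.clear()
        if self._spill is not None:
            self._write(self._spill, split_index, ordinal, tag, payload)
        else:
            self._items.append((split_index, ordinal, tag, payload))
            self._bytes += len(payload)

    @staticmethod
    def _write(fh, split_index, ordinal, tag, payload) -> None:
        fh.write(_SPOOL_HEADER.pack(split_index, ordinal, tag, len(payload)))
        fh.write(payload)

    def items(self) -> List[Tuple[int, int, int, bytes]]:
        if self._spill is None:
            return list(self._items)
        self._spill.flush()
        out = []
        with open(self._spill.name, "rb") as fh:
            while True:
                head = fh.read(_SPOOL_HEADER.size)
                if not head:
                    break
                si, o, tag, n = _SPOOL_HEADER.unpack(head)
                out.append((si, o, tag, fh.read(n)))
        return out

    def close(self) -> None:
        if self._spill is not None:
            self._spill.close()
            os.unlink(self._spill.name)
            self._spill = None


def _grouped_pairs(spool: _ReducerSpool) -> Tuple[List[bytes], List[bytes], int, int]:
    """Sort a reducer's items, group by (split_index, ordinal) and verify
    each group holds exactly one record per file.  Returns (forward payloads,
    reverse payloads, group count, pair count)."""
    items = sorted(spool.items(), key=lambda it: (it[0], it[1], it[2]))
    forward: List[bytes] = []
    reverse: List[bytes] = []
    groups = 0
    i = 0
    while i < len(items):
        key = items[i][:2]
        group = [it for it in items[i:i + 2] if it[:2] == key]
        rest = i + len(group)
        if rest < len(items) and items[rest][:2] == key:
            raise JoinError(f"group {key} has more than 2 members")
        if len(group) != 2 or {group[0][2], group[1][2]} != {1, 2}:
            raise JoinError(
                f"group (split {key[0]}, ordinal {key[1]}) has "
                f"{len(group)} member(s); expected one record per file"
            )
        forward.append(group[0][3])
        reverse.append(group[1][3])
        groups += 1
        i = rest
    return forward, reverse, groups, len(forward)


def run_paired_reduceside(config: RunConfig) -> ShardSet:
    """Paired run via an explicit map/shuffle/reduce pipeline.

    Stage 1 scans every split of each file independently (single-end record
    reading); stage 2 partitions items by ``split_index mod n_reducers`` and
    groups by ``(split_index, ordinal)``; stage 3 feeds each reducer's pairs,
    in key order, to one aligner instance.
    """
    if config.mode != "paired" or config.join_strategy != "reduce_side":
        raise ValueError(
            "run_paired_reduceside requires mode='paired', join_strategy='reduce_side'"
        )
    composites = plan_tasks(config)
    n_reducers = max(1, min(len(composites), config.n_workers))
    output_dir = Path(config.output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    tmp_dir = output_dir / ".shuffle"
    tmp_dir.mkdir(exist_ok=True)
    per_reducer = config.shuffle_memory_budget // n_reducers
    spools = [_ReducerSpool(per_reducer, tmp_dir) for _ in range(n_reducers)]

    from .seqformats import serialize_record

    try:
        # stage 1: map analog — independent single-file split scans
        for comp in composites:
            for tag, split in ((1, comp.left), (2, comp.right)):
                for ordinal, rec in read_split(split, config.fmt):
                    spools[comp.index % n_reducers].add(
                        comp.index, ordinal, tag, serialize_record(rec)
                    )

        # stage 2: shuffle analog — group by key within each reducer
        grouping_ops = 0
        task_args = []
        for r, spool in enumerate(spools):
            forward, reverse, groups, pairs = _grouped_pairs(spool)
            grouping_ops += groups
            task_args.append((r, 2, [iter(forward), iter(reverse)], pairs))

        # stage 3: reduce analog — one aligner per reducer
        return _execute(config, task_args, grouping_ops=grouping_ops)
    finally:
        for spool in spools:
            spool.close()
        shutil.rmtree(tmp_dir, ignore_errors=True)


def run(config: RunConfig) -> ShardSet:
    """Dispatch to the mode/strategy the config selects."""
    if config.mode == "single":
        return run_single_end(config)
    if config.join_strategy == "map_side":
        return run_paired_mapside(config)
    return run_paired_reduceside(config)
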