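"""Named-pipe IPC with an external aligner process.

A task hands its reads to the aligner and collects the aligner's SAM output
without touching the disk: the reads are written into one or two FIFO
special files while the output is concurrently drained from a third.  FIFO
kernel buffers are small (~64 KiB), and a full buffer blocks its writer, so
every channel must make progress independently — a sequential
feed-then-drain loop provably deadlocks as soon as the child produces more
output than one buffer before consuming all input.  Each channel is
therefore serviced by its own thread.

Open-ordering hazards are avoided by never blocking inside ``open``: feed
ends are opened ``O_WRONLY|O_NONBLOCK`` in a retry loop (``ENXIO`` until the
child attaches its read end, aborted if the child exits first) and the drain
end is opened ``O_RDONLY|O_NONBLOCK`` (which always succeeds).  A child that
dies mid-stream surfaces as ``EPIPE`` on the feed side or end-of-stream on
the drain side; the run then fails fast with the child's exit code and
stderr tail, and the FIFOs are removed.
"""

from __future__ import annotations

import errno
import os
import select
import subprocess
import threading
import time
import uuid
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import BinaryIO, Iterable, List, Optional, Sequence, Tuple, Union

from .seqformats import SequenceRecord, serialize_record

__all__ = [
    "Direction",
    "FifoEndpoint",
    "PumpReport",
    "IpcError",
    "PipeRunError",
    "PipeTimeout",
    "make_fifo_set",
    "remove_fifo_set",
    "fifo_session",
    "run_piped",
]

_CHUNK = 1 << 16


class IpcError(OSError):
    pass


class PipeRunError(RuntimeError):
    """The child process failed or a channel broke."""

    def __init__(self, message: str, exit_code: Optional[int] = None,
                 side: Optional[str] = None, stderr_tail: str = ""):
        detail = message
        if exit_code is not None:
            detail += f" (exit code {exit_code})"
        if stderr_tail:
            detail += f"\n--- child stderr tail ---\n{stderr_tail}"
        super().__init__(detail)
        self.exit_code = exit_code
        self.side = side
        self.stderr_tail = stderr_tail


class PipeTimeout(PipeRunError):
    pass


class Direction(Enum):
    FEED = "feed"    # this tool writes, the child reads
    DRAIN = "drain"  # the child writes, this tool reads


@dataclass(frozen=True)
class FifoEndpoint:
    path: Path
    direction: Direction


@dataclass(frozen=True)
class PumpReport:
    records_fed: Tuple[int, ...]
    bytes_drained: int
    child_exit_code: int


def make_fifo_set(workdir: Union[str, Path], n_inputs: int) -> List[FifoEndpoint]:
    """Create *n_inputs* FEED FIFOs plus one DRAIN FIFO under *workdir*.

    Names are collision-free; all paths are genuine FIFO special files.
    Raises :class:`IpcError` naming the path on platforms or directories
    where FIFO creation fails.
    """
    if n_inputs not in (1, 2):
        raise ValueError(f"n_inputs must be 1 or 2, got {n_inputs}")
    workdir = Path(workdir)
    token = uuid.uuid4().hex[:12]
    endpoints: List[FifoEndpoint] = []
    names = [f"feed{i + 1}-{token}.fifo" for i in range(n_inputs)]
    names.append(f"drain-{token}.fifo")
    dirs = [Direction.FEED] * n_inputs + [Direction.DRAIN]
    try:
        for name, direction in zip(names, dirs):
            path = workdir / name
            os.mkfifo(path)
            endpoints.append(FifoEndpoint(path=path, direction=direction))
    except (OSError, AttributeError) as exc:
        remove_fifo_set(endpoints)
        raise IpcError(f"cannot create FIFO under {workdir}: {exc}") from exc
    return endpoints


def remove_fifo_set(endpoints: Iterable[FifoEndpoint]) -> None:
    for ep in endpoints:
        try:
            os.unlink(ep.path)
        except FileNotFoundError:
            pass


class fifo_session:
    """Context manager owning a FIFO set; unlinks the FIFOs on exit."""

    def __init__(self, workdir: Union[str, Path], n_inputs: int):
        self.workdir = Path(workdir)
        self.n_inputs = n_inputs
        self.endpoints: List[FifoEndpoint] = []

    def __enter__(self) -> List[FifoEndpoint]:
        self.endpoints = make_fifo_set(self.workdir, self.n_inputs)
        return self.endpoints

    def __exit__(self, *exc_info) -> None:
        remove_fifo_set(self.endpoints)
        self.endpoints = []


def _serialize_item(item) -> bytes:
    if isinstance(item, (bytes, bytearray)):
        return bytes(item)
    if isinstance(item, SequenceRecord):
        return serialize_record(item)
    raise TypeError(f"feeder items must be bytes or SequenceRecord, got {type(item)}")


def _feed_worker(ep: FifoEndpoint, items: Iterable, counter: List[int],
                 errors: List, proc: subprocess.Popen, stop: threading.Event) -> None:
    fd = None
    try:
        while True:  # non-blocking open retry: ENXIO until the child attaches
            try:
                fd = os.open(ep.path, os.O_WRONLY | os.O_NONBLOCK)
                break
            except OSError as exc:
                if exc.errno != errno.ENXIO:
                    raise
            if stop.is_set():
                return
            if proc.poll() is not None:
                errors.append(("feed", ep, "child exited before opening its input"))
                return
            time.sleep(0.002)
        os.set_blocking(fd, True)
        with os.fdopen(fd, "wb", buffering=_CHUNK) as writer:
            fd = None
            for item in items:
                if stop.is_set():
                    return
                writer.write(_serialize_item(item))
                counter[0] += 1
    except BrokenPipeError:
        if not stop.is_set():
            errors.append(("feed", ep, "child closed its input mid-stream"))
    except Exception as exc:  # noqa: BLE001 - reported to the main thread
        errors.append(("feed", ep, repr(exc)))
    finally:
        if fd is not None:
            os.close(fd)


def _drain_worker(ep: Optional[FifoEndpoint], source, sink: BinaryIO,
                  total: List[int], errors: List,
                  proc: subprocess.Popen, stop: threading.Event) -> None:
    try:
        if ep is None:
            # stdout-capture mode: `source` is the child's stdout pipe
            while True:
                chunk = source.read(_CHUNK)
                if not chunk:
                    return
                sink.write(chunk)
                total[0] += len(chunk)
        fd = os.open(ep.path, os.O_RDONLY | os.O_NONBLOCK)
        try:
            while True:
                try:
                    chunk = os.read(fd, _CHUNK)
                except BlockingIOError:
                    # writer attached but no data yet
                    select.select([fd], [], [], 0.05)
                    continue
                if chunk:
                    sink.write(chunk)
                    total[0] += len(chunk)
                elif proc.poll() is not None or stop.is_set():
                    return  # pipe empty and no writer will come back
                else:
                    time.sleep(0.002)  # child alive, has not opened its output yet
        finally:
            os.close(fd)
    except Exception as exc:  # noqa: BLE001
        errors.append(("drain", ep, repr(exc)))


def run_piped(
    command: Sequence[str],
    feeders: Sequence[Tuple[FifoEndpoint, Iterable]],
    drain: Tuple[Optional[FifoEndpoint], BinaryIO],
    timeout: Optional[float] = None,
    stderr_path: Optional[Union[str, Path]] = None,
) -> PumpReport:
    """Run *command* while servicing every FIFO channel concurrently.

    ``feeders`` maps each FEED endpoint to a finite iterable of
    :class:`SequenceRecord` or pre-serialized ``bytes``; each channel is
    closed (end-of-stream) after its last item.  ``drain`` is the DRAIN
    endpoint and a binary sink — pass ``(None, sink)`` to capture the child's
    standard output instead of a FIFO.  The child's stderr goes to
    *stderr_path* (a log file) when given, else is captured in memory for
    diagnostics; it is never merged into the drained stream.

    Returns a :class:`PumpReport` after the child exits.  Raises
    :class:`PipeTimeout` (after terminating the child) when *timeout* is
    exceeded, and :class:`PipeRunError` on nonzero exit or a broken channel,
    distinguishing feed-side from drain-side failure.
    """
    drain_ep, sink = drain
    stop = threading.Event()
    errors: List = []
    counters = [[0] for _ in feeders]
    drained = [0]

    stderr_file = None
    if stderr_path is not None:
        stderr_file = open(stderr_path, "wb")
        stderr_target = stderr_file
    else:
        stderr_target = subprocess.PIPE

    proc = subprocess.Popen(
        list(command),
        stdin=subprocess.DEVNULL,
        stdout=subprocess.PIPE if drain_ep is None else subprocess.DEVNULL,
        stderr=stderr_target,
    )
    threads = []
    try:
        for (ep, items), counter in zip(feeders, counters):
            t = threading.Thread(
                target=_feed_worker, args=(ep, items, counter, errors, proc, stop),
                daemon=True,
            )
            t.start()
            threads.append(t)
        t = threading.Thread(
            target=_drain_worker,
            args=(drain_ep, proc.stdout, sink, drained, errors, proc, stop),
            daemon=True,
        )
        t.start()
        threads.append(t)

        try:
            exit_code = proc.wait(timeout=timeout)
        except subprocess.TimeoutExpired:
            stop.set()
            proc.kill()
            proc.wait()
            _join_all(threads)
            raise PipeTimeout(
                f"child exceeded {timeout} s and was terminated", side="timeout"
            ) from None

        _join_all(threads)
    finally:
        stop.set()
        if proc.poll() is None:
            proc.kill()
            proc.wait()
        stderr_tail = _stderr_tail(proc, stderr_file, stderr_path)
        if stderr_file is not None:
            stderr_file.close()

    if exit_code != 0:
        raise PipeRunError(
            f"aligner process failed: {' '.join(map(str, command))}",
            exit_code=exit_code, stderr_tail=stderr_tail,
        )
    if errors:
        side, ep, msg = errors[0]
        where = f" on {ep.path}" if ep is not None else ""
        raise PipeRunError(
            f"{side}-side channel failure{where}: {msg}",
            exit_code=exit_code, side=side, stderr_tail=stderr_tail,
        )
    return PumpReport(
        records_fed=tuple(c[0] for c in counters),
        bytes_drained=drained[0],
        child_exit_code=exit_code,
    )


def _join_all(threads, deadline: float = 30.0) -> None:
    end = time.monotonic() + deadline
    for t in threads:
        t.join(max(0.0, end - time.monotonic()))


def _stderr_tail(proc, stderr_file, stderr_path, limit: int = 4096) -> str:
    data = b""
    if stderr_file is not None:
        stderr_file.flush()
        try:
            with open(stderr_path, "rb") as fh:
                fh.seek(max(0, os.path.getsize(stderr_path) - limit))
                data = fh.read()
        except OSError:
            pass
    elif proc.stderr is not None:
        try:
            data = proc.stderr.read() or b""
        except (OSError, ValueError):
            data = b""
        data = data[-limit:]
    return data.decode("utf-8", errors="replace")
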