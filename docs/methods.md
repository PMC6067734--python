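# Methods

This note records the procedures splitalign implements, the assumptions
they rest on, the parameters that matter, and the numerical/design choices
made where the design was genuinely open.

## Input model

Inputs are single- or paired-end read sets in FASTQ or FASTA, plain or
compressed with gzip or bzip2.  FASTQ is taken to be the strict 4-line
dialect: header, bases, `+` separator, qualities.  Multi-line FASTQ is
rejected, deliberately — record-boundary synchronization at an arbitrary
byte offset is only well-defined when records have a fixed 4-line period.
The `+` line's optional repeated header is accepted on input and never
regenerated, so serialization is canonical and byte-level equivalence
checks are meaningful.  `\r\n` is tolerated on input with `\r` stripped;
output uses `\n` only.  Compression is detected from magic bytes
(`1f 8b` for gzip, `BZh` for bzip2), never from file extensions.

## Split planning and boundary synchronization

A plain file of `S` bytes with split size `s` is divided into the
contiguous byte ranges `[k·s, min((k+1)·s, S))`.  With automatic sizing the
split size is `ceil(S / n_workers)`, so the number of tasks equals the
worker count whenever the file has enough records.  Compressed files are
one split each: gzip has no random access, and bzip2 block-boundary
splitting is a project of its own, excluded here.

Synchronization maps a byte offset to the first record header at or after
it.  FASTA: the next line starting `>`.  FASTQ: a line *L* starting `@` is
accepted iff line *L*+2 starts `+` and lines *L*+1 and *L*+3 have equal
content length.  This rule cannot be fooled by a quality line that begins
with `@`: for such a candidate, the line two below is the next record's
bases line, which never starts `+`.  The residual failure mode is a file in
which a quality line *and* the three lines after it jointly mimic a full
record with matching lengths; this requires adversarial construction beyond
quality-sigil collisions and is a documented limitation (the synthetic
adversarial generator produces heterogeneous read lengths precisely so this
cannot occur in the test corpus).  A region in which no candidate validates
before end of file yields ownership of zero records — never a guessed
offset.

Ownership is half-open on header offsets: split *i* owns the records whose
header lies in `[sync(start_i), sync(start_{i+1}))`.  A record whose body
crosses the split's end is read in full by its owner.  Keys handed to
downstream consumers are per-split 0-based ordinals (the global identity of
a read is `(split index, ordinal)`, which is what the reduce-side join
keys on).

## Paired-end composites

The correctness of paired alignment rests on the one-to-one correspondence
between the two input files.  Splitting both files at the same byte offsets
preserves that correspondence only when the files are byte-symmetric, which
real files (differing id decorations, descriptions) are not.  splitalign
therefore derives the reverse file's split points from record ordinals: the
forward file is byte-split and synced, its cumulative ownership counts
`c_0=0, c_1, …` are computed, and one streaming pass over the reverse file
records the byte offset of each record `c_i`.  Composite *i* then owns
ordinals `[c_i, c_{i+1})` in both files unconditionally, at the cost of one
extra pass.  A forward split that owns zero records maps to an empty byte
range on the reverse side (the one case where a split's `start == end`).

Total-record-count disagreement between the files fails fast with both
counts.  Read-id verification (comparing stems after stripping `/1`/`/2`)
is available but off by default: it costs a full read of both files and the
ordinal construction does not need it.

The composite record stream emits, per pair, the serialized forward read
concatenated with the serialized reverse read, keyed by the byte length of
the forward part — slicing the value at the key recovers both ends exactly.
The forward read's length was chosen for the key; either end would do, but
the choice must be fixed and documented for consumers.

## Pipe IPC

Each task creates its FIFOs (`mkfifo`) in a private directory that contains
nothing else — the feed/drain path never touches a regular file.  The child
aligner is launched with the FIFO paths substituted into its command
template.  Concurrency contract: every channel is serviced by a dedicated
thread, because FIFO kernel buffers are ~64 KiB and a full buffer blocks
its writer; progress on each channel must be independent of the others.
The stress test drives this with a child that writes 10 MiB before reading
any input.

Open-ordering is handled without blocking opens: writers open
`O_WRONLY|O_NONBLOCK` in a retry loop (ENXIO until the child attaches,
abandoned if the child exits first), readers open `O_RDONLY|O_NONBLOCK`
(always succeeds) and poll.  A child death mid-stream surfaces as EPIPE on
the feed side or end-of-stream on the drain side; the run fails fast with
the exit code and a stderr tail, FIFOs are unlinked, and partial shards are
removed.  The child's stderr goes to a per-task log file, never into the
SAM stream.  There is no default timeout for real runs (alignment runtime
is unbounded); tests and the acceptance script pass explicit timeouts.
One caveat of in-memory stderr capture (used only when no log path is
given): a child emitting more stderr than one pipe buffer before exiting
could stall, which is why the engine always passes a log file.

## Execution modes

*Single-end* is map-only: one aligner per synced split, records streamed in
file order, shard written concurrently, no grouping or sorting anywhere
(the run result carries a `grouping_ops` counter asserting this).
*Paired map-side* is identical but feeds two FIFOs by cutting each
composite value at its key; a small lock-guarded splitter advances the
underlying stream only when a side's buffer is empty, so memory is bounded
by the consumers' skew (one FIFO buffer for an aligner that reads its two
inputs in step).  *Paired reduce-side* is the deliberately naive
comparison strategy: independent single-file split scans emit
`((split_index, ordinal), file_tag, serialized_record)`; items are
partitioned by `split_index mod n_reducers` — any pair-preserving
partitioner is admissible; this is the simplest deterministic one — and
grouped by key, each group required to hold exactly one record per file;
each reducer feeds its groups, in key order, to one aligner.  The shuffle
buffer spills to per-reducer temporary files past a memory budget (default
256 MiB), so the strategy retains the disk character of a real
shuffle.  Reducer count is the number of forward-file splits capped at
`n_workers` — the choice is free; this keeps reducer parallelism aligned
with worker parallelism.

Tasks run in a pool of exactly `n_workers` slots (a gauge records the peak
concurrent aligner count); each aligner may use `threads_per_worker`
threads, giving two-level parallelism.  An optional per-aligner memory
estimate, multiplied by the worker count, is checked against detected
system memory (`sysconf`) before anything launches.  Failure handling is
fail-fast with no retry: retry semantics belong to a cluster framework,
not to this library.

With a deterministic aligner the merged, position-sorted output is
invariant under worker count and join strategy — the equivalence suites
bind to the bundled mock aligner.  Real spliced aligners such as HISAT2
collect splice sites while processing reads, so their output is
split-dependent; comparisons across worker counts for a real aligner go
through the statistics vector and the misalignment fraction with
tolerances, not byte equality (an informational test does this when HISAT2
is installed).

## Aligner adapter and mock aligner

An aligner is described by a YAML config: executable, single- and
paired-end argument templates over the placeholder set
`{index} {input1} {input2} {output} {threads} {format}`, per-format option
tokens, and a flag for aligners that write SAM to stdout.  Unknown
placeholders and missing mandatory fields are config errors.  Command
construction is pure textual substitution (tokens that substitute to the
empty string are dropped), so identical inputs always produce identical
argument vectors.  The shipped HISAT2 config restricts itself to
long-stable options (`-x -U -1 -2 -S -p -f`).

The mock aligner is a genuine external executable (`python -m
splitalign.mock_aligner`, also installed as `splitalign-mock-aligner`), not
an in-process shortcut, so tests exercise the real process-launch path.
Per read it reports the leftmost exact occurrence of the bases on the
forward strand of the first reference sequence containing one, else the
same for the reverse complement (FLAG 16, SEQ/QUAL stored
reverse-complemented), else unmapped.  Mapped records carry MAPQ 60,
CIGAR `<len>M`, `NM:i:0`, `NH:i:1`.  In paired mode the two inputs are
read alternately one record at a time (keeping two-FIFO feeding in
lockstep) and pair/mate flag bits, `RNEXT =` and TLEN are emitted; proper
insert-size modelling is out of scope — the flags carry exactly the
information the statistics module consumes.

## Statistics

`merge_sam` is a pure copy-merge (first shard's header, concatenated
bodies) and refuses shards whose `@SQ` sets differ.  Sorting is a separate
operation because equivalence checks need position-sorted bodies while
merged output should preserve shard order.

`compute_stats` definitions, where a choice had to be made:
`uniquely_mapped_reads` counts primary mapped records with `NH:i:1` when
the NH tag is present, else falls back to reads whose QNAME+end occurs
exactly once among *all* mapped records (secondary included);
`bases_mapped` sums M/=/X/I CIGAR bases of primary mapped records,
excluding soft clips; `average_quality` assumes Phred+33 and averages over
all primary records; `average_coverage` divides mapped bases by the total
`@SQ` reference length (whole-reference baseline).  Rates with an empty
denominator are reported as undefined, not zero.  Relative differences
between two runs are `(b − a)/a` in percent, negative meaning the second
run is smaller; a zero baseline marks the metric undefined.

`misalignment_fraction` takes the reads uniquely mapped in *both* files and
reports the fraction whose (reference, 1-based position) differ; reads
unique in only one file are excluded from the denominator, and an empty
intersection is undefined.

## Synthetic data

The generator is deterministic to the byte from an integer seed (integer
RNG draws only; gzip written with `mtime=0`).  Defaults: reference 5000 bp
of uniform random bases in one sequence (`chrT`); 500 reads of length 70;
paired mode samples a fragment of `2·L + inner_distance` (default inner
distance 60) and emits the forward end and the reverse-complemented far
end; qualities are the constant `I` so mean quality is exactly 40.  These
sizes keep each engine run in the hundreds of milliseconds while giving
every split configuration multiple records per split; the statistical
content of the tests (exact counts, invariances) does not depend on scale.

`unmappable_fraction` replaces exactly `round(f · n_slots)` read slots with
random sequence verified absent from both reference strands, so unmapped
counts and alignment rates are exact by construction, not in expectation.
A sidecar manifest records per-read ground truth (position, strand,
mappability).  Paired generation can pad the reverse file's descriptions
with seeded random-length filler (`asymmetric_layout`) to force different
byte layouts in the two files, which is what makes the ordinal-based
pairing observable.

What the generator does *not* emulate: sequencing errors, quality-score
distributions, splicing, duplicated or repetitive genomes.  The mock
aligner is exact-match, so error realism would add nothing testable; the
consequence is that passing tests demonstrate the correctness of the
splitting/piping/joining/merging machinery, not the behaviour of any real
aligner on real data.  Repeat-induced ambiguity (a read occurring twice in
the reference) is statistically negligible at the default read lengths
(probability on the order of `S²·4^−L`) and would affect only manifest
positions, not any invariant.

The adversarial FASTQ generator gives every quality string a leading run
of `@` or `+` characters and heterogeneous read lengths (5–40 bp), the
combination under which naive sigil-scanning misidentifies record starts
but the validated synchronization rule provably cannot.

## Problem sizes used in verification

The test suite and acceptance script run entirely on generated data:
200 randomized (file, split size) completeness cases; exhaustive
byte-by-byte synchronization sweeps over ≤10 KiB adversarial files;
pairing checks at five split sizes over 300 byte-asymmetric pairs; a
10 MiB pipe stream compared byte-for-byte against file-based invocation
plus a 10 MiB early-burst child; 20 random 1000-pair fixtures for join
strategy equivalence; worker counts {1, 2, 4} across all three modes; and
gzip/bzip2 twins checked end-to-end against plain input.  These sizes were
chosen as the smallest at which every mechanism (multi-split files,
multi-record splits, buffer-exceeding pipe payloads, spilled shuffles) is
genuinely exercised.
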