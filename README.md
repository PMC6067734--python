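# splitalign

Scatter-gather read alignment for single-machine parallelism: **splitalign**
runs many instances of an unmodified external aligner concurrently over
byte-range splits of FASTQ/FASTA inputs, streams reads to each instance
through POSIX named pipes (no intermediate files), and copy-merges the SAM
shards back into one file with a mapping-statistics report.

It is aimed at people who align RNA-seq (or any short-read) datasets with a
splice-aware aligner such as HISAT2 and want the splitting/joining/merging
machinery of a distributed mapping pipeline — record-boundary-safe input
splits, paired-end synchronization, deadlock-free pipe IPC — as an ordinary,
testable Python library and CLI.

## What it does

**Record-boundary-safe splitting.** An input file is cut into byte ranges of
a chosen size; each split's start is synchronized forward to the first true
record header at or after it, and a record belongs to the split whose synced
half-open range `[sync(start_i), sync(start_{i+1}))` contains its header
offset.  The union of all split streams therefore equals the whole-file
parse for *any* split size — including FASTQ files whose quality strings
begin with `@`.  A candidate `@` line at offset *L* is accepted as a header
only if line *L*+2 starts with `+` and lines *L*+1 and *L*+3 have equal
length; a quality line can never pass this test because the line two below
it is a bases line.

**Paired-end composite splits.** The two files of a paired dataset carry a
one-to-one read correspondence, but byte-symmetric splitting silently breaks
it when the files differ in byte layout.  splitalign splits the forward
file by bytes, computes its per-split record counts `c_i`, and locates the
reverse file's split points by streaming to the same record ordinals, so
composite *i* owns identical read ordinals in both files unconditionally.
Each composite yields `(key, value)` items where `value` is the serialized
forward read immediately followed by the reverse read and `key` is the byte
length of the forward part.

**Named-pipe IPC.** Each task creates one or two FEED FIFOs and a DRAIN
FIFO, launches the aligner with the FIFO paths substituted into a
config-file command template, and services every channel from its own
thread.  Because a FIFO's kernel buffer is small and a full buffer blocks
its writer, feeding and draining sequentially deadlocks; concurrent
servicing is the contract, verified against a child that writes 10 MiB of
output before reading any input.

**Two paired-end join strategies.** The *map-side* join pairs the ends
while reading composite splits (a map-only pipeline, like single-end mode);
the *reduce-side* join scans each file independently, groups records by
`(split index, ordinal)` key, and aligns per group — kept for comparison,
and required to produce byte-identically the same position-sorted merged
output.

**Merging and statistics.** Shards are copy-merged (one header,
concatenated bodies, no re-sorting).  `compute_stats` extracts the metric
vector used to compare two runs of the same read set — alignments,
secondary alignments, reads mapped/unmapped, uniquely mapped reads
(NH tag), alignment rate, CIGAR-mapped bases, NM mismatches, error rate,
mean base quality, coverage — and `misalignment_fraction` reports how many
reads uniquely mapped in both of two SAM files landed on a different
reference or position.

A deterministic exact-match **mock aligner** ships with the package (config
`mock`): it maps each read to the leftmost exact occurrence on either
strand of the reference and emits valid SAM, so the whole pipeline is
testable hermetically and its output is analytically predictable.

## Worked example

Generate a synthetic reference and 1000 reads of length 70, 10% of which
are verified at generation time to occur nowhere on either strand, then
align with 4 concurrent mock-aligner instances:

```sh
splitalign fixtures reference --seed 1 --length 4000 --out-dir .
splitalign fixtures reads --seed 1 --reference ref-seed1.fasta \
    --n-reads 1000 --read-length 70 --unmappable-fraction 0.1 --out-dir .
splitalign --single -1 reads-seed1.fastq --index ref-seed1.fasta \
    --aligner mock --out run --na 4 --merge
splitalign stats run/merged.sam
```

which prints:

```
4 shard(s) written to run
merged: run/merged.sam
alignments               900
secondary alignments     0
reads unmapped           100
reads mapped             900
reads mapped and paired  0
uniquely mapped reads    900
alignment rate           0.9
bases mapped             63000
mismatches               0
error rate               0
average quality          40
average coverage         15.75
```

Exactly the 900 mappable reads map (the mock aligner is exact-match, so
`alignment rate` is 900/1000 = 0.9 by construction), each contributing its
70 bases to `bases mapped` (900 × 70 = 63 000); qualities are the constant
`I` (Phred 40); coverage is 63 000 mapped bases over the 4000 bp reference.
Running the same command with `--na 1` produces an identical
position-sorted merged body — worker count never changes the result with a
deterministic aligner.

For a real aligner, point `--aligner` at a config file; the shipped
`hisat2` config uses only long-stable options (`-x -1 -2 -U -S -p -f`), so
any HISAT2 version with a built index works:

```sh
splitalign --paired -1 r_1.fastq -2 r_2.fastq --index idx/genome \
    --aligner hisat2 --out run --na 4 --nt 2 --merge
```

## Scope

Single-machine by design: the distributed-filesystem and cluster-scheduling
layers of a Hadoop-style deployment (block placement, locality hints,
resource negotiation, task retry) are out of scope; the algorithmic content
— splitting, synchronization, pairing, piping, joining, merging — is all
here.  gzip/bzip2 inputs are supported but never byte-split (one split per
compressed file).  Multi-line FASTQ is rejected; SAM is the only output
format.
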