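# Bundled deterministic exact-match mock aligner (ships with splitalign).
# Invoked through the interpreter so it works without the console script
# being on PATH.
name: mock
executable: python -m splitalign.mock_aligner
single_end_template: "--ref {index} --in {input1} --out {output}"
paired_end_template: "--ref {index} --in {input1} --in2 {input2} --out {output}"
stdout_mode: false
format_flags:
  fastq: ""
  fasta: ""
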