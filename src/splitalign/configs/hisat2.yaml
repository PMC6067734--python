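# HISAT2 invocation using only long-stable command-line options
# (-x, -U, -1, -2, -S, -p, -f), so the adapter stays version-agnostic.
name: hisat2
executable: hisat2
single_end_template: "{format} -p {threads} -x {index} -U {input1} -S {output}"
paired_end_template: "{format} -p {threads} -x {index} -1 {input1} -2 {input2} -S {output}"
stdout_mode: false
format_flags:
  fastq: ""
  fasta: "-f"
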