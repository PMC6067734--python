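"""Stress child for the pipe pump: writes a large burst of output *before*
reading any input, then copies the input to the output.

A sequential feed-then-drain caller provably stalls against this child as
soon as the burst exceeds one FIFO kernel buffer; a caller that services
every channel concurrently must complete.  Run as::

    python -m splitalign._burst_child --in IN --out OUT --burst-bytes N
"""

import argparse
import sys


def main(argv=None) -> int:
    parser = argparse.ArgumentParser()
    parser.add_argument("--in", dest="inp", required=True)
    parser.add_argument("--out", required=True)
    parser.add_argument("--burst-bytes", type=int, default=10 << 20)
    args = parser.parse_args(argv)

    block = b"B" * 65536
    with open(args.out, "wb") as out:
        remaining = args.burst_bytes
        while remaining > 0:
            n = min(remaining, len(block))
            out.write(block[:n])
            remaining -= n
        with open(args.inp, "rb") as inp:
            while True:
                chunk = inp.read(65536)
                if not chunk:
                    break
                out.write(chunk)
    return 0


if __name__ == "__main__":
    sys.exit(main())
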