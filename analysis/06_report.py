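#!/usr/bin/env python
"""Render the Markdown summary report for the completed run."""

from pathlib import Path

from maosel.pipeline import report

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    print(report(OUTDIR))


if __name__ == "__main__":
    main()
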