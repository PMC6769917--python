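#!/usr/bin/env python
"""Reduce the HAI dilution plates to a saccharide x lectin MIC table with
">" censoring, mirroring the layout of an inhibition-assay summary.

Writes results/hai_report.tsv.
"""

from pathlib import Path

from facprof.hai import hai_report, read_hai_csv

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = read_hai_csv(RESULTS / "hai_plates.csv")
    report = hai_report(records)
    report.to_csv(RESULTS / "hai_report.tsv", sep="\t")
    print(report.to_string())
    print(f"-> {RESULTS / 'hai_report.tsv'}")


if __name__ == "__main__":
    main()
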