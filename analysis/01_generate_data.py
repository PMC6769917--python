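#!/usr/bin/env python
"""Generate the synthetic study inputs: the 130-glycan archetype panel and
the HAI dilution plates for the classic inhibitor set.

Writes results/panel.tsv, results/hai_plates.csv and prints the panel's
class composition (61 N-linked across five classes, 39 glycolipid-type).
"""

from pathlib import Path

import pandas as pd

from facprof import class_counts, make_archetype_panel, simulate_hai_plate, write_panel
from facprof.glycan_panel import n_linked_count

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"

# (saccharide, lectin, true MIC mM, plate start mM): trehalose and
# isomaltose inhibit the strong paralog in the single-digit mM range,
# GlcNAc is the mannose-binder's best inhibitor, maltose inhibits nothing
PLATES = [
    ("Trehalose", "PPL2A", 7.0, 250.0),
    ("Isomaltose", "PPL2A", 7.0, 250.0),
    ("Trehalose", "PPL3", 20.0, 200.0),
    ("Isomaltose", "PPL3", 10.0, 200.0),
    ("N-Acetyl-D-glucosamine", "PPL4", 5.0, 200.0),
    ("Trehalose", "PPL4", 90.0, 200.0),
    ("Maltose", "PPL2A", 1000.0, 250.0),
    ("Maltose", "PPL3", 1000.0, 200.0),
]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    panel = make_archetype_panel(SEED)
    write_panel(panel, RESULTS / "panel.tsv")
    print(f"panel: {len(panel)} glycans -> {RESULTS / 'panel.tsv'}")
    print(f"  N-linked: {n_linked_count(panel)}; classes: {class_counts(panel)}")

    rows = []
    for sacch, lectin, true_mic, start in PLATES:
        series = simulate_hai_plate(true_mic, start, seed=SEED)
        rows.append({
            "saccharide": sacch, "lectin": lectin,
            "start_conc": start, "unit": "mM",
            "outcomes": "".join("1" if o else "0" for o in series.outcomes),
        })
    pd.DataFrame(rows).to_csv(RESULTS / "hai_plates.csv", index=False)
    print(f"HAI plates: {len(rows)} series -> {RESULTS / 'hai_plates.csv'}")


if __name__ == "__main__":
    main()
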