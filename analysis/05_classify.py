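#!/usr/bin/env python
"""Classify the archetype profiles into mJRL specificity groups and
compare the strong/weak paralog pair.

Expected outcome: the two complex-type binders fall in group A subgroup 1,
the mannose/chitin binder in group A unclassified, and the paralog pair is
rank-concordant with a ~100-fold global offset discordant only at the
plant-core glycan 017.

Writes results/classification.json.
"""

import json
from pathlib import Path

from facprof import classify_mjrl, compare_profiles, load_panel
from facprof.profiling import load_profile

RESULTS = Path(__file__).resolve().parents[1] / "results"
ARCHETYPES = ("PPL2A_like", "PPL3_like", "PPL4_like")


def main() -> None:
    panel = load_panel(RESULTS / "panel.tsv")
    profiles = {n: load_profile(RESULTS / f"profile_{n}.json") for n in ARCHETYPES}

    report = {"assignments": [], "comparisons": []}
    for name, prof in profiles.items():
        asg = classify_mjrl(prof, panel)
        report["assignments"].append({
            "lectin": name, "group": asg.group, "subgroup": asg.subgroup,
            "evidence": asg.evidence,
        })
        print(f"{name}: group {asg.group}, subgroup {asg.subgroup}")

    pair = ("PPL2A_like", "PPL3_like")
    res = compare_profiles(profiles[pair[0]], profiles[pair[1]], panel)
    report["comparisons"].append({"pair": list(pair), **res})
    print(f"{pair[0]} vs {pair[1]}: concordance {res['concordance']:.4f}, "
          f"median log10 offset {res['median_log10_offset']:.2f}, "
          f"discordant {res['discordant']}")

    with open(RESULTS / "classification.json", "w") as fh:
        json.dump(report, fh, indent=1)
    print(f"-> {RESULTS / 'classification.json'}")


if __name__ == "__main__":
    main()
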