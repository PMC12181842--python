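#!/usr/bin/env python
"""Stage 2: body-first / brain-first classification and stability.

Reads visits.csv and hc_reference.csv from stage 1; writes labels.csv
(per-visit labels of all three systems), labels_autonomic.csv (the
autonomic-only sensitivity variant) and stability.csv.
"""
import argparse
from pathlib import Path

import pandas as pd

from socpd.phenotyping import HCReference, SEVERITY_ORDERS, classify_table, stability_analysis


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/analysis")
    args = ap.parse_args()

    out = Path(args.out)
    visits = pd.read_csv(out / "visits.csv")
    hc_ref = HCReference.from_frame(pd.read_csv(out / "hc_reference.csv"))

    labels = classify_table(visits, hc_ref, mode="full")
    labels.to_csv(out / "labels.csv", index=False)
    labels_aut = classify_table(visits, hc_ref, mode="autonomic_only")
    labels_aut.to_csv(out / "labels_autonomic.csv", index=False)

    base = labels[labels["time_years"] == 0]
    print("baseline SOC labels:")
    print(base["soc"].value_counts().to_string())
    both = base.merge(
        labels_aut[labels_aut["time_years"] == 0][["subject_id", "soc"]],
        on="subject_id", suffixes=("_full", "_autonomic"),
    )
    agree = (both["soc_full"] == both["soc_autonomic"]).mean()
    print(f"full vs autonomic-only baseline agreement: {100 * agree:.1f}%")

    frames = []
    for system in ("soc", "cognition", "motor"):
        stab = stability_analysis(labels, SEVERITY_ORDERS[system], label_col=system)
        stab.insert(0, "system", system)
        frames.append(stab)
    stability = pd.concat(frames, ignore_index=True)
    stability.to_csv(out / "stability.csv", index=False)
    last = stability.groupby("system").last()
    print("reclassification at the last visit (% of baseline):")
    print(last[["time_years", "wrong_pct", "progression_pct", "stable_pct", "missing_pct"]]
          .round(1).to_string())


if __name__ == "__main__":
    main()
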