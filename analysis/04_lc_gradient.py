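#!/usr/bin/env python
"""Stage 4: locus coeruleus connectopic gradients and SMS profiles.

Reads the LC connectivity fixtures from stage 3, computes each
subject's dominant gradient and similarity-with-middle-section (SMS)
profile, compares groups with a percentile bootstrap, and back-projects
one example subject's gradient extremes to the cortical parcels.
"""
import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from socpd.lc_gradient import backproject, bootstrap_compare, subject_sms


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", default="results/analysis")
    ap.add_argument("--n-boot", type=int, default=2000)
    args = ap.parse_args()

    out = Path(args.out)
    conn_dir = out / "lc_connectivity"
    meta = json.loads((conn_dir / "meta.json").read_text())
    stacked = np.load(conn_dir / "connectivity.npy")
    voxel_z = np.array(meta["voxel_z"])
    labels = pd.read_csv(out / "labels.csv")
    base = labels[labels["time_years"] == 0][["subject_id", "soc"]].rename(
        columns={"soc": "phenotype"}
    )

    frames = []
    for sid, mat in zip(meta["subjects"], stacked):
        prof = subject_sms(mat, voxel_z)
        prof.insert(0, "subject_id", sid)
        frames.append(prof)
    sms = pd.concat(frames, ignore_index=True).merge(base, on="subject_id")
    sms.to_csv(out / "sms.csv", index=False)

    body = sms[sms["phenotype"] == "body_first"]
    brain = sms[sms["phenotype"] == "brain_first"]
    comp = bootstrap_compare(body, brain, n_boot=args.n_boot, seed=args.seed)
    comp.to_csv(out / "sms_group_comparison.csv", index=False)
    print("mean normalized SMS by phenotype and region:")
    print(sms.groupby(["phenotype", "region"])["sms_normalized"].mean().round(3).to_string())
    print("bootstrap group difference (body-first - brain-first) per section:")
    print(comp.round(4).to_string(index=False))

    bp = backproject(stacked[0], voxel_z)
    bp.insert(0, "subject_id", meta["subjects"][0])
    bp.to_csv(out / "backprojection_example.csv", index=False)
    print("example back-projection labels:", bp["label"].value_counts().to_dict())


if __name__ == "__main__":
    main()
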