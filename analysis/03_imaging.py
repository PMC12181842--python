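#!/usr/bin/env python
"""Stage 3: striatal SBR and DTI-ALPS indices from imaging fixtures.

Generates the derived-quantity imaging fixtures for the classified
subjects, computes the specific binding ratio and the ALPS index, and
writes sbr.csv, alps.csv plus the LC connectivity inputs for stage 4.
"""
import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from socpd.imaging import add_alps, add_sbr
from socpd.synth import CohortConfig, generate_imaging


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", default="results/analysis")
    args = ap.parse_args()

    out = Path(args.out)
    labels = pd.read_csv(out / "labels.csv")
    base = labels[labels["time_years"] == 0][["subject_id", "soc"]].rename(
        columns={"soc": "phenotype"}
    )
    fix = generate_imaging(CohortConfig(seed=args.seed), base)

    sbr = add_sbr(fix.sbr_table)
    alps = add_alps(fix.alps_table)
    sbr.to_csv(out / "sbr.csv", index=False)
    alps.to_csv(out / "alps.csv", index=False)

    conn_dir = out / "lc_connectivity"
    conn_dir.mkdir(exist_ok=True)
    stacked = np.stack([fix.lc_connectivity[s] for s in sorted(fix.lc_connectivity)])
    np.save(conn_dir / "connectivity.npy", stacked)
    (conn_dir / "meta.json").write_text(json.dumps({
        "subjects": sorted(fix.lc_connectivity),
        "voxel_z": [int(z) for z in fix.lc_voxel_z],
    }))

    merged = sbr.merge(base, on="subject_id")
    print("mean SBR by phenotype and hemisphere:")
    print(merged.groupby(["phenotype", "hemisphere"])["sbr"].mean().round(3).to_string())
    merged_a = alps.merge(base, on="subject_id")
    print("mean ALPS by phenotype and hemisphere:")
    print(merged_a.groupby(["phenotype", "hemisphere"])["alps_index"].mean().round(3).to_string())


if __name__ == "__main__":
    main()
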