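#!/usr/bin/env python
"""Stage 5: longitudinal mixed models, survival analysis, mediation.

Fits group x time mixed models per cohort and outcome with BH FDR over
the interaction p-values, Cox models for PD conversion (prodromal) and
the MoCA<21 dementia endpoint (clinical), and the glymphatic mediation
analysis (phenotype -> less-affected ALPS -> UPDRS III).
"""
import argparse
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from socpd.models import dementia_endpoint, fdr_adjust, fit_cox, fit_trajectory, mediate

OUTCOMES = ("updrs2", "updrs3", "moca", "gds")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", default="results/analysis")
    args = ap.parse_args()

    out = Path(args.out)
    visits = pd.read_csv(out / "visits.csv")
    labels = pd.read_csv(out / "labels.csv")
    base = labels[labels["time_years"] == 0][["subject_id", "soc"]].rename(
        columns={"soc": "phenotype"}
    )
    mv = visits.merge(base, on="subject_id")

    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cohort, dfc in mv.groupby("cohort"):
            for outcome in OUTCOMES:
                res = fit_trajectory(dfc, outcome, comparison_level="body_first")
                res.insert(0, "cohort", cohort)
                frames.append(res)
    traj = pd.concat(frames, ignore_index=True)
    inter = (traj["term"] == "group:time").to_numpy()
    adj = np.full(len(traj), np.nan)
    adj[inter], _ = fdr_adjust(traj.loc[inter, "p"].to_numpy())
    traj["p_fdr"] = adj
    traj.to_csv(out / "trajectories.csv", index=False)
    print("group x time interaction estimates (body-first vs brain-first):")
    print(traj[inter][["cohort", "outcome", "beta", "se", "p_fdr"]]
          .round(4).to_string(index=False))

    prod = mv[mv["cohort"] == "prodromal"]
    conv = prod[prod["time_years"] == 0][
        ["subject_id", "phenotype", "age", "sex", "education",
         "converted_to_pd", "conversion_time"]
    ].rename(columns={"conversion_time": "duration", "converted_to_pd": "event"})
    conv["event"] = conv["event"].astype(int)
    clin = mv[mv["cohort"] == "clinical"]
    dem = dementia_endpoint(clin).merge(
        clin[clin["time_years"] == 0][["subject_id", "phenotype", "age", "sex", "education"]],
        on="subject_id",
    )
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for endpoint, table in (("pd_conversion", conv), ("dementia_moca_below_21", dem)):
            r = fit_cox(table, comparison_level="body_first")
            r.pop("schoenfeld_p")
            r["endpoint"] = endpoint
            rows.append(r)
            print(f"{endpoint}: HR {r['hr']:.3f} (95% CI {r['ci_low']:.3f}-{r['ci_high']:.3f}), "
                  f"p={r['p']:.2e}, events {r['n_events']}/{r['n']}")
    pd.DataFrame(rows).to_csv(out / "survival.csv", index=False)

    alps = pd.read_csv(out / "alps.csv")
    med_df = (
        alps[alps["hemisphere"] == "less_affected"][["subject_id", "alps_index"]]
        .merge(mv[mv["time_years"] == 0][["subject_id", "phenotype", "updrs3", "age", "sex"]],
               on="subject_id")
    )
    med_df["exposure"] = (med_df["phenotype"] == "body_first").astype(float)
    med = mediate(med_df, "exposure", "alps_index", "updrs3",
                  covariates=("age", "sex"), seed=args.seed)
    med_out = {
        "indirect": med.indirect, "direct": med.direct, "total": med.total,
        "proportion_mediated_pct": 100.0 * med.proportion_mediated,
        "ci_low": med.ci_low, "ci_high": med.ci_high, "p": med.p,
        "opposite_signs": med.opposite_signs,
    }
    (out / "mediation.json").write_text(json.dumps(med_out, indent=2, sort_keys=True))
    note = (" [indirect and direct effects have opposite signs; the proportion"
            " is not interpretable]" if med.opposite_signs else "")
    print(f"mediation (phenotype -> ALPS -> UPDRS III): indirect {med.indirect:.4f}, "
          f"proportion {100 * med.proportion_mediated:.1f}%, p={med.p:.3f}{note}")


if __name__ == "__main__":
    main()
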