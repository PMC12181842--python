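#!/usr/bin/env python
"""Stage 1: simulate the healthy-control reference and the case cohorts.

Writes hc_reference.csv, hc_visits.csv and visits.csv into the results
directory; later stages read from the same directory.
"""
import argparse
from pathlib import Path

from socpd.synth import CohortConfig, generate_cohort, generate_reference_controls


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", default="results/analysis")
    ap.add_argument("--n-prodromal", type=int, default=500)
    ap.add_argument("--n-clinical", type=int, default=500)
    ap.add_argument("--n-hc", type=int, default=263)
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    cfg = CohortConfig(
        n_hc=args.n_hc,
        n_prodromal=args.n_prodromal,
        n_clinical=args.n_clinical,
        seed=args.seed,
    )
    hc_ref, hc_visits = generate_reference_controls(cfg)
    visits = generate_cohort(cfg, hc_ref)

    hc_ref.to_frame().to_csv(out / "hc_reference.csv", index=False)
    hc_visits.to_csv(out / "hc_visits.csv", index=False)
    visits.to_csv(out / "visits.csv", index=False)
    n_subj = visits["subject_id"].nunique()
    print(f"cohort: {n_subj} case subjects, {len(visits)} visits -> {out}/visits.csv")
    print(f"reference: {args.n_hc} controls -> {out}/hc_reference.csv")


if __name__ == "__main__":
    main()
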