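"""Phenotype classification and longitudinal stability.

The primary classification follows the Synuclein Origin and Connectome
(SOC) model: a subject whose REM-sleep-behaviour questionnaire (RBDSQ)
or autonomic-symptom scale (SCOPA-AUT) score lies at least one standard
deviation above the mean of a healthy-control reference group — on
either scale, or both — is labelled body-first; subjects within the
normal range on both scales are brain-first. A sensitivity mode uses
autonomic symptoms alone. Comparator classifications (tremor-dominant
vs non-tremor-dominant; cognitively normal vs mild cognitive
impairment) and a reclassification-stability analysis are included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from socpd.scales import COGNITIVE_TESTS, SOC_SCALES

__all__ = [
    "HCReference",
    "classify_soc",
    "classify_motor",
    "classify_cognition",
    "classify_table",
    "stability_analysis",
    "SEVERITY_ORDERS",
]


@dataclass(frozen=True)
class HCReference:
    """Per-scale healthy-control summary defining classification thresholds.

    ``stats`` maps scale name to ``(mean, sd, n)``. The body-first
    threshold of a scale is ``mean + 1*sd``; cognitive impairment is
    judged on z-scores against the same reference. Thresholds are
    computed once from the control sample and never re-estimated from
    the case cohort.
    """

    stats: Mapping[str, tuple[float, float, int]]

    def __post_init__(self):
        for name, (_, sd, n) in self.stats.items():
            if sd < 0:
                raise ValueError(f"negative SD for {name}")
            if n < 2:
                raise ValueError(f"reference for {name} based on n < 2")

    def mean(self, scale: str) -> float:
        return self.stats[scale][0]

    def sd(self, scale: str) -> float:
        return self.stats[scale][1]

    def threshold(self, scale: str) -> float:
        """Body-first trigger threshold: one SD above the control mean."""
        m, sd, _ = self.stats[scale]
        return m + sd

    def z(self, scale: str, score: float) -> float:
        m, sd, _ = self.stats[scale]
        if sd == 0:
            raise ZeroDivisionError(f"degenerate reference for {scale} (sd=0)")
        return (score - m) / sd

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, m, sd, n) for k, (m, sd, n) in self.stats.items()],
            columns=["scale", "mean", "sd", "n"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HCReference":
        return cls(
            {r.scale: (float(r.mean), float(r.sd), int(r.n)) for r in df.itertuples()}
        )


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


def classify_soc(visit: Mapping, hc_ref: HCReference, mode: str = "full") -> str:
    """Classify one visit as ``body_first`` / ``brain_first``.

    ``mode='full'`` uses both the RBDSQ and SCOPA-AUT; a score at or
    above the control mean + 1 SD on either scale triggers body-first
    (equality counts, the rule being "greater or equal").
    ``mode='autonomic_only'`` is the sensitivity variant using
    SCOPA-AUT alone. A missing required score yields ``unclassifiable``
    rather than a silent default.
    """
    if mode not in ("full", "autonomic_only"):
        raise ValueError(f"unknown mode {mode!r}")
    scales = SOC_SCALES if mode == "full" else ("scopa_aut",)
    values = [visit.get(s) if hasattr(visit, "get") else visit[s] for s in scales]
    if any(_is_missing(v) for v in values):
        return "unclassifiable"
    for scale, value in zip(scales, values):
        if value >= hc_ref.threshold(scale):
            return "body_first"
    return "brain_first"


def classify_motor(visit: Mapping) -> str:
    """Tremor-dominant vs non-tremor-dominant by resting-tremor presence."""
    flag = visit.get("resting_tremor_present") if hasattr(visit, "get") else visit["resting_tremor_present"]
    if _is_missing(flag):
        return "unclassifiable"
    return "tremor_dominant" if bool(flag) else "non_tremor_dominant"


def classify_cognition(
    visit: Mapping,
    hc_ref: HCReference,
    z_cut: float = 1.5,
    n_impaired_min: int = 2,
) -> str:
    """Cognitively normal vs mild cognitive impairment (level-I rule).

    A subject is MCI when at least ``n_impaired_min`` cognitive tests
    fall ``z_cut`` SDs or more below the healthy-control mean. Fewer
    than ``n_impaired_min`` observed tests -> ``unclassifiable``.
    """
    observed, impaired = 0, 0
    for test in COGNITIVE_TESTS:
        v = visit.get(test) if hasattr(visit, "get") else visit[test]
        if _is_missing(v):
            continue
        observed += 1
        # Compared on the score scale (score <= mean - z_cut * sd) so a
        # score exactly at the cut counts as impaired without
        # floating-point division artifacts.
        if hc_ref.sd(test) == 0:
            raise ZeroDivisionError(f"degenerate reference for {test} (sd=0)")
        if v <= hc_ref.mean(test) - z_cut * hc_ref.sd(test):
            impaired += 1
    if observed < n_impaired_min:
        return "unclassifiable"
    return "mci" if impaired >= n_impaired_min else "normal"


def classify_table(
    visits: pd.DataFrame,
    hc_ref: HCReference,
    mode: str = "full",
    z_cut: float = 1.5,
    n_impaired_min: int = 2,
) -> pd.DataFrame:
    """Apply all three classifications to every row of a visit table."""
    out = visits[["subject_id", "time_years"]].copy()
    records = visits.to_dict("records")
    out["soc"] = [classify_soc(r, hc_ref, mode) for r in records]
    out["motor"] = [classify_motor(r) for r in records]
    out["cognition"] = [
        classify_cognition(r, hc_ref, z_cut, n_impaired_min) for r in records
    ]
    out["mode"] = mode
    return out


#: Higher rank = more severe phenotype (a shift downward is a "wrong"
#: reclassification; upward shifts reflect disease progression).
SEVERITY_ORDERS = {
    "soc": {"brain_first": 0, "body_first": 1},
    "cognition": {"normal": 0, "mci": 1},
    "motor": {"tremor_dominant": 0, "non_tremor_dominant": 1},
}


def stability_analysis(
    labels_by_visit: pd.DataFrame,
    severity_order: Mapping[str, int],
    label_col: str = "soc",
) -> pd.DataFrame:
    """Longitudinal reclassification stability of one labelling system.

    The classification rule is applied de novo at each time point; the
    baseline label is the one at the earliest visit. At every follow-up
    time the percentage of baseline-classified subjects now holding a
    less severe label ("wrong" reclassification), a more severe label
    (progression), the same label (stable), or no classifiable label
    (missing) is reported. The denominator is always the entire
    baseline-classifiable population, so the four percentages sum
    to 100.
    """
    df = labels_by_visit[["subject_id", "time_years", label_col]].copy()
    times = sorted(df["time_years"].unique())
    if len(times) < 2:
        raise ValueError("stability analysis needs at least two time points")
    t0 = times[0]
    base = df[df["time_years"] == t0]
    base = base[base[label_col].isin(severity_order)]
    baseline = dict(zip(base["subject_id"], base[label_col]))
    n0 = len(baseline)
    if n0 == 0:
        raise ValueError("no classifiable subjects at baseline")

    rows = []
    for t in times[1:]:
        now = df[df["time_years"] == t]
        now = dict(zip(now["subject_id"], now[label_col]))
        wrong = progressed = stable = missing = 0
        for sid, lab0 in baseline.items():
            lab = now.get(sid)
            if lab is None or lab not in severity_order:
                missing += 1
            elif severity_order[lab] < severity_order[lab0]:
                wrong += 1
            elif severity_order[lab] > severity_order[lab0]:
                progressed += 1
            else:
                stable += 1
        rows.append(
            {
                "time_years": t,
                "baseline_n": n0,
                "wrong_pct": 100.0 * wrong / n0,
                "progression_pct": 100.0 * progressed / n0,
                "stable_pct": 100.0 * stable / n0,
                "missing_pct": 100.0 * missing / n0,
            }
        )
    return pd.DataFrame(rows)
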