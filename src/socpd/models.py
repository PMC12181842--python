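"""Longitudinal and survival modelling, FDR control, mediation.

Trajectories are compared with linear mixed-effects models (fixed
effects for group, time, their interaction, age, sex, disease duration
and — for cognitive outcomes — education; random intercepts per
subject, REML). Conversion to PD and the dementia endpoint (first visit
with MoCA strictly below 21) are modelled with Cox proportional-hazards
regression adjusted for age, sex and education, with the proportional-
hazards assumption checked via scaled Schoenfeld residuals. Families of
p-values are controlled at q = 0.05 by the Benjamini-Hochberg step-up.
Mediation uses the product-of-coefficients decomposition with a
percentile bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test

__all__ = [
    "fit_trajectory",
    "fit_cox",
    "dementia_endpoint",
    "fdr_adjust",
    "mediate",
    "MediationResult",
]

#: Outcomes whose trajectory models additionally adjust for education.
COGNITIVE_OUTCOMES = {"moca", "sdmt", "hvlt_recall", "lns", "semantic_fluency", "benton"}


def fit_trajectory(
    data: pd.DataFrame,
    outcome: str,
    group_col: str = "phenotype",
    time_col: str = "time_years",
    covariates: tuple[str, ...] = ("age", "sex", "disease_duration"),
    subject_col: str = "subject_id",
    add_education_for_cognitive: bool = True,
    comparison_level: str | None = None,
) -> pd.DataFrame:
    """Linear mixed model of ``outcome`` with a group x time interaction.

    Returns a tidy frame with one row per fixed effect (beta, SE, z, p).
    The row of interest for differential progression is
    ``term == 'group:time'``. ``comparison_level`` chooses which group
    level is coded 1 (default: last in sort order). Raises on a
    singular / non-converged fit.
    """
    covs = list(covariates)
    if add_education_for_cognitive and outcome in COGNITIVE_OUTCOMES and "education" in data:
        covs.append("education")
    covs = [c for c in covs if c in data.columns]
    df = data[[subject_col, outcome, group_col, time_col, *covs]].dropna()
    constant = [c for c in covs if df[c].nunique() <= 1]
    if constant:
        # A constant covariate is collinear with the intercept (e.g. disease
        # duration in a cohort enrolled at diagnosis) and would make the
        # design singular.
        warnings.warn(f"dropping constant covariate(s): {constant}")
        covs = [c for c in covs if c not in constant]
        df = df.drop(columns=constant)
    if df[subject_col].nunique() < 3:
        raise ValueError("too few subjects for a mixed model")
    df = df.copy()
    levels = sorted(df[group_col].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"expected a binary group column, got levels {levels}")
    if comparison_level is not None:
        if str(comparison_level) not in levels:
            raise ValueError(f"{comparison_level!r} not among group levels {levels}")
        levels = [l for l in levels if l != str(comparison_level)] + [str(comparison_level)]
    df["_group"] = (df[group_col].astype(str) == levels[-1]).astype(float)
    df["_time"] = df[time_col].astype(float)
    rhs = " + ".join(["_group * _time", *covs]) if covs else "_group * _time"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(f"{outcome} ~ {rhs}", df, groups=df[subject_col])
        try:
            fit = model.fit(reml=True, method="lbfgs")
        except np.linalg.LinAlgError as e:  # pragma: no cover - defensive
            raise RuntimeError(f"singular mixed-model fit: {e}")
    if not np.all(np.isfinite(fit.params)):
        raise RuntimeError("mixed-model fit did not converge (non-finite estimates)")
    rename = {"_group": "group", "_time": "time", "_group:_time": "group:time"}
    rows = []
    for name in fit.fe_params.index:
        rows.append(
            {
                "outcome": outcome,
                "term": rename.get(name, name),
                "beta": float(fit.fe_params[name]),
                "se": float(fit.bse_fe[name]),
                "p": float(fit.pvalues[name]),
                "group_reference": levels[0],
                "group_comparison": levels[-1],
            }
        )
    return pd.DataFrame(rows)


def dementia_endpoint(
    visits: pd.DataFrame,
    moca_col: str = "moca",
    cutoff: float = 21.0,
    subject_col: str = "subject_id",
    time_col: str = "time_years",
) -> pd.DataFrame:
    """Time to PD dementia: first visit with MoCA strictly below ``cutoff``.

    A subject whose MoCA is exactly at the cutoff never triggers the
    event. Subjects without an event are censored at their last
    observed visit.
    """
    rows = []
    for sid, g in visits.sort_values(time_col).groupby(subject_col):
        below = g[g[moca_col] < cutoff]
        if len(below):
            rows.append({subject_col: sid, "duration": float(below[time_col].iloc[0]), "event": 1})
        else:
            rows.append({subject_col: sid, "duration": float(g[time_col].iloc[-1]), "event": 0})
    return pd.DataFrame(rows)


def fit_cox(
    data: pd.DataFrame,
    duration_col: str = "duration",
    event_col: str = "event",
    group_col: str = "phenotype",
    covariates: tuple[str, ...] = ("age", "sex", "education"),
    comparison_level: str | None = None,
) -> dict:
    """Cox proportional-hazards model for a binary phenotype contrast.

    Returns the hazard ratio for the group term with its 95% CI and
    p-value, plus a scaled-Schoenfeld proportionality check per
    covariate (a violation warns, it does not fail).
    ``comparison_level`` chooses the level coded 1. Raises when either
    group has no events or everything is censored.
    """
    covs = [c for c in covariates if c in data.columns]
    df = data[[duration_col, event_col, group_col, *covs]].dropna().copy()
    levels = sorted(df[group_col].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"expected a binary group column, got levels {levels}")
    if comparison_level is not None:
        if str(comparison_level) not in levels:
            raise ValueError(f"{comparison_level!r} not among group levels {levels}")
        levels = [l for l in levels if l != str(comparison_level)] + [str(comparison_level)]
    df["_group"] = (df[group_col].astype(str) == levels[-1]).astype(float)
    events_by_group = df.groupby("_group")[event_col].sum()
    if df[event_col].sum() == 0:
        raise ValueError("no events observed; Cox model is undefined")
    if (events_by_group < 1).any():
        raise ValueError("need at least one event per group")
    df = df.drop(columns=[group_col])
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    ph = proportional_hazard_test(cph, df, time_transform="rank")
    ph_p = {str(k): float(v) for k, v in ph.summary["p"].items()}
    violated = [k for k, v in ph_p.items() if v < 0.05]
    if violated:
        warnings.warn(f"proportional-hazards check flagged: {violated}")
    s = cph.summary.loc["_group"]
    return {
        "hr": float(np.exp(s["coef"])),
        "ci_low": float(np.exp(s["coef lower 95%"])),
        "ci_high": float(np.exp(s["coef upper 95%"])),
        "p": float(s["p"]),
        "n": int(len(df)),
        "n_events": int(df[event_col].sum()),
        "group_reference": levels[0],
        "group_comparison": levels[-1],
        "schoenfeld_p": ph_p,
        "ph_ok": not violated,
    }


def fdr_adjust(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(adjusted, reject)`` where ``adjusted`` are monotone BH
    adjusted p-values and ``reject`` flags discoveries at level ``q``.
    Empty input yields empty output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    ranked = p[order] * m / ranks
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    # Step-up rejection computed multiplicatively (p_(k) * m <= k * q),
    # so a p exactly on the BH boundary is rejected regardless of
    # floating-point division order.
    passing = np.nonzero(p[order] * m <= ranks * q)[0]
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    return adjusted, reject


@dataclass
class MediationResult:
    a: float  # exposure -> mediator
    b: float  # mediator -> outcome | exposure
    indirect: float  # a * b
    direct: float  # c'
    total: float  # a*b + c'
    proportion_mediated: float  # a*b / (a*b + c')
    ci_low: float
    ci_high: float
    p: float
    opposite_signs: bool
    n_boot: int


def mediate(
    data: pd.DataFrame,
    exposure: str,
    mediator: str,
    outcome: str,
    covariates: tuple[str, ...] = (),
    n_boot: int = 2000,
    seed: int = 0,
) -> MediationResult:
    """Product-of-coefficients mediation with a percentile bootstrap.

    Fits ``mediator ~ exposure (+ covariates)`` for the a-path and
    ``outcome ~ exposure + mediator (+ covariates)`` for the b-path and
    direct effect c'. The indirect effect is a*b; the proportion
    mediated is a*b / (a*b + c'), flagged (not clamped) when indirect
    and direct effects have opposite signs. The bootstrap CI and the
    two-sided p-value refer to the indirect effect.
    """
    if n_boot < 500:
        warnings.warn("fewer than 500 bootstrap iterations for mediation")
    covs = [c for c in covariates if c in data.columns]
    df = data[[exposure, mediator, outcome, *covs]].dropna().reset_index(drop=True)
    n = len(df)
    if n < 10:
        raise ValueError("too few complete cases for mediation")

    x = df[exposure].to_numpy(dtype=float)
    m_vec = df[mediator].to_numpy(dtype=float)
    y_vec = df[outcome].to_numpy(dtype=float)
    C = df[covs].to_numpy(dtype=float) if covs else np.empty((n, 0))
    ones = np.ones((n, 1))
    Xa = np.column_stack([ones, x[:, None], C])
    Xb = np.column_stack([ones, x[:, None], m_vec[:, None], C])

    def _paths(rows) -> tuple[float, float, float]:
        coef_a = np.linalg.lstsq(Xa[rows], m_vec[rows], rcond=None)[0]
        coef_b = np.linalg.lstsq(Xb[rows], y_vec[rows], rcond=None)[0]
        return float(coef_a[1]), float(coef_b[2]), float(coef_b[1])

    all_rows = np.arange(n)
    a, b, c_prime = _paths(all_rows)
    indirect = a * b
    total = indirect + c_prime
    proportion = indirect / total if total != 0 else np.nan

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        ab, bb, _ = _paths(idx)
        boot[i] = ab * bb
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    p_pos = (np.sum(boot <= 0) + 1) / (n_boot + 1)
    p_neg = (np.sum(boot >= 0) + 1) / (n_boot + 1)
    p = min(1.0, 2 * min(p_pos, p_neg))
    return MediationResult(
        a=a,
        b=b,
        indirect=indirect,
        direct=c_prime,
        total=total,
        proportion_mediated=proportion,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p=float(p),
        opposite_signs=bool(indirect * c_prime < 0),
        n_boot=n_boot,
    )
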