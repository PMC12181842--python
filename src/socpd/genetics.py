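"""SNP quality control, phenotype association, permutation FDR.

Quality control removes, in order: subjects with more than 5% missing
genotypes, SNPs with a call rate below 85%, and SNPs violating
Hardy-Weinberg equilibrium at p < 0.01 (a deliberately lenient
threshold that retains informative markers). Association with the
binary body-first/brain-first phenotype uses per-SNP logistic
regression with additive dosage coding, adjusted for age and sex.
Family-wise error is controlled by permutation: phenotype labels (with
their covariates) are permuted against the genotype matrix, per-SNP
permutation p-values are computed from the covariate-adjusted score
statistic, and Benjamini-Hochberg at 0.05 is applied to the permutation
p-values (a max-T variant is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from socpd.models import fdr_adjust, fit_trajectory

__all__ = [
    "hwe_test",
    "qc_filter",
    "associate_phenotype",
    "permutation_fdr",
    "progression_by_genotype",
    "QCReport",
]


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """One-degree-of-freedom chi-square test of Hardy-Weinberg equilibrium.

    Expected genotype counts come from the estimated allele frequency.
    Returns ``(chi2, p)``. A monomorphic SNP is assigned p = 1 by
    convention (and chi2 = 0).
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("no genotyped subjects")
    p_hat = (2 * counts[0] + counts[1]) / (2 * n)
    if p_hat in (0.0, 1.0):
        return 0.0, 1.0  # monomorphic: HWE trivially satisfied
    expected = n * np.array([p_hat**2, 2 * p_hat * (1 - p_hat), (1 - p_hat) ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return chi2, float(scipy.stats.chi2.sf(chi2, df=1))


@dataclass
class QCReport:
    """What the quality-control pass removed, in its documented order."""

    subjects_removed_missing: list = field(default_factory=list)
    snps_removed_callrate: list = field(default_factory=list)
    snps_removed_hwe: list = field(default_factory=list)
    n_subjects_kept: int = 0
    n_snps_kept: int = 0
    subject_missing_max: float = 0.05
    snp_callrate_min: float = 0.85
    hwe_p_min: float = 0.01

    def to_dict(self) -> dict:
        return {
            "subjects_removed_missing": list(self.subjects_removed_missing),
            "snps_removed_callrate": list(self.snps_removed_callrate),
            "snps_removed_hwe": list(self.snps_removed_hwe),
            "n_subjects_kept": self.n_subjects_kept,
            "n_snps_kept": self.n_snps_kept,
            "thresholds": {
                "subject_missing_max": self.subject_missing_max,
                "snp_callrate_min": self.snp_callrate_min,
                "hwe_p_min": self.hwe_p_min,
            },
        }


def qc_filter(
    genotypes: pd.DataFrame,
    subject_missing_max: float = 0.05,
    snp_callrate_min: float = 0.85,
    hwe_p_min: float = 0.01,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the QC cascade and return the filtered matrix plus a report.

    Order: subjects with more than ``subject_missing_max`` missing
    genotypes, then SNPs with call rate strictly below
    ``snp_callrate_min`` (among surviving subjects), then SNPs with a
    Hardy-Weinberg p-value strictly below ``hwe_p_min``. Idempotent:
    a second pass removes nothing. Raises if nothing survives.
    """
    if genotypes.empty:
        raise ValueError("empty genotype matrix")
    g = genotypes.copy()
    miss_frac = g.isna().mean(axis=1)
    bad_subjects = list(g.index[miss_frac > subject_missing_max])
    g = g.drop(index=bad_subjects)
    if g.empty:
        raise ValueError("all subjects removed by missingness filter")

    call_rate = g.notna().mean(axis=0)
    bad_callrate = list(g.columns[call_rate < snp_callrate_min])
    g = g.drop(columns=bad_callrate)

    bad_hwe = []
    for snp in g.columns:
        col = g[snp].dropna().to_numpy()
        n_aa_ref = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_alt = int((col == 2).sum())
        _, p = hwe_test(n_aa_ref, n_het, n_alt)
        if p < hwe_p_min:
            bad_hwe.append(snp)
    g = g.drop(columns=bad_hwe)
    if g.shape[1] == 0:
        raise ValueError("all SNPs removed by QC")
    report = QCReport(
        subjects_removed_missing=bad_subjects,
        snps_removed_callrate=bad_callrate,
        snps_removed_hwe=bad_hwe,
        n_subjects_kept=g.shape[0],
        n_snps_kept=g.shape[1],
        subject_missing_max=subject_missing_max,
        snp_callrate_min=snp_callrate_min,
        hwe_p_min=hwe_p_min,
    )
    return g, report


def _ridge_logit(y: np.ndarray, X: np.ndarray, lam: float = 1.0, n_iter: int = 50):
    """Weakly penalized Newton logistic fit (fallback under separation)."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        H = X.T @ (X * W[:, None]) + lam * np.eye(X.shape[1])
        grad = X.T @ (y - mu) - lam * beta
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1 - mu)
    cov = np.linalg.inv(X.T @ (X * W[:, None]) + lam * np.eye(X.shape[1]))
    se = np.sqrt(np.diag(cov))
    return beta, se


def associate_phenotype(
    genotypes: pd.DataFrame,
    labels: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-SNP logistic association with the binary phenotype.

    Additive dosage coding; covariates (age, sex) adjusted. Returns a
    frame with log-odds ``beta``, ``se``, Wald ``p`` and a
    ``separation`` flag; separated or non-converged SNPs fall back to a
    weakly ridge-penalized Newton fit (flagged). Constant-dosage SNPs
    are excluded with a warning.
    """
    common = genotypes.index.intersection(labels.index)
    g = genotypes.loc[common]
    y_all = labels.loc[common].astype(float)
    if not set(np.unique(y_all)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    C = covariates.loc[common] if covariates is not None else pd.DataFrame(index=common)
    rows = []
    for snp in g.columns:
        col = g[snp]
        ok = col.notna()
        dose = col[ok].to_numpy(dtype=float)
        if np.all(dose == dose[0]):
            warnings.warn(f"constant dosage for {snp}; excluded from association")
            continue
        y = y_all[ok].to_numpy()
        X = np.column_stack([np.ones(ok.sum()), dose, C.loc[ok.values].to_numpy(dtype=float)]) \
            if len(C.columns) else np.column_stack([np.ones(ok.sum()), dose])
        separated = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            beta, se = fit.params[1], fit.bse[1]
            if not np.isfinite(se) or se > 50:
                raise np.linalg.LinAlgError("unstable fit")
        except Exception:
            separated = True
            params, ses = _ridge_logit(y, X)
            beta, se = params[1], ses[1]
        z = beta / se
        rows.append(
            {
                "snp": snp,
                "beta": float(beta),
                "se": float(se),
                "p": float(2 * scipy.stats.norm.sf(abs(z))),
                "n": int(ok.sum()),
                "separation": separated,
            }
        )
    return pd.DataFrame(rows)


def _score_stats(G: np.ndarray, resid: np.ndarray, w: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Covariate-adjusted efficient score statistic per SNP column.

    ``resid`` and ``w`` come from the null logistic fit of labels on
    covariates only; missing genotypes are mean-imputed per SNP for the
    statistic (they carry zero score weight in expectation).
    """
    U = G.T @ resid
    XtWX = X.T @ (X * w[:, None])
    XtWX_inv = np.linalg.inv(XtWX)
    GW = G * w[:, None]
    gwx = GW.T @ X  # (snps, k)
    v_full = (G * GW).sum(axis=0)
    V = v_full - np.einsum("ij,jk,ik->i", gwx, XtWX_inv, gwx)
    V = np.maximum(V, 1e-12)
    return U**2 / V


def permutation_fdr(
    assoc_results: pd.DataFrame,
    genotypes: pd.DataFrame,
    labels: pd.Series,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 5000,
    seed: int = 0,
    q: float = 0.05,
    method: str = "bh",
) -> pd.DataFrame:
    """Permutation p-values per SNP with FDR control at ``q``.

    Phenotype labels (together with their covariate rows) are permuted
    against the genotype matrix; the per-SNP statistic is the
    covariate-adjusted score statistic, whose null fit is reused across
    permutations. Permutation p = (1 + #{perm stat >= observed}) /
    (1 + n_perm), hence always at least 1/(n_perm + 1).
    ``method='bh'`` applies Benjamini-Hochberg to the permutation
    p-values; ``method='maxt'`` uses the max-statistic family-wise
    bound instead.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    common = genotypes.index.intersection(labels.index)
    g = genotypes.loc[common]
    y = labels.loc[common].astype(float).to_numpy()
    C = covariates.loc[common].to_numpy(dtype=float) if covariates is not None else np.empty((len(common), 0))
    X = np.column_stack([np.ones(len(common)), C])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null_fit = sm.Logit(y, X).fit(disp=0)
    mu = null_fit.predict(X)
    w = mu * (1 - mu)
    resid = y - mu

    G = g.to_numpy(dtype=float)
    col_mean = np.nanmean(G, axis=0)
    inds = np.where(np.isnan(G))
    G[inds] = np.take(col_mean, inds[1])
    G = G - G.mean(axis=0)  # centering stabilizes the score statistic

    obs = _score_stats(G, resid, w, X)
    rng = np.random.default_rng(seed)
    n = len(y)
    exceed = np.zeros_like(obs)
    max_null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        stats = _score_stats(G, resid[perm], w[perm], X[perm])
        exceed += stats >= obs
        max_null[b] = stats.max()
    p_perm = (1.0 + exceed) / (1.0 + n_perm)

    keep = [s for s in g.columns if s in set(assoc_results["snp"])]
    out = assoc_results.set_index("snp").loc[keep].reset_index(names="snp")
    order = {s: i for i, s in enumerate(g.columns)}
    out["p_perm"] = [p_perm[order[s]] for s in out["snp"]]
    if method == "bh":
        adj, reject = fdr_adjust(out["p_perm"].to_numpy(), q=q)
        out["p_perm_adj"] = adj
        out["significant"] = reject
    elif method == "maxt":
        stat_by_snp = {s: obs[order[s]] for s in out["snp"]}
        out["p_maxt"] = [
            (1.0 + np.sum(max_null >= stat_by_snp[s])) / (1.0 + n_perm) for s in out["snp"]
        ]
        out["significant"] = out["p_maxt"] <= q
    else:
        raise ValueError(f"unknown method {method!r}")
    return out


def progression_by_genotype(
    visits: pd.DataFrame,
    genotype_groups: pd.Series,
    outcome: str,
    covariates: tuple[str, ...] = ("age", "sex", "education"),
) -> pd.DataFrame:
    """Mixed-model progression contrast between genotype groups.

    ``genotype_groups`` maps subject_id to a binary group label (e.g.
    heterozygous vs others); non-missing subjects must be partitioned
    into exactly two groups of at least 2 subjects each. Delegates to
    the trajectory mixed model with genotype as the group factor.
    """
    groups = genotype_groups.dropna()
    sizes = groups.value_counts()
    if len(sizes) != 2 or (sizes < 2).any():
        raise ValueError("need two genotype groups with at least 2 subjects each")
    df = visits.merge(
        groups.rename("genotype_group"), left_on="subject_id", right_index=True
    )
    return fit_trajectory(
        df,
        outcome,
        group_col="genotype_group",
        covariates=covariates,
    )
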