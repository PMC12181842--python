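"""Locus coeruleus connectopic gradient analysis.

From a voxels x parcels functional-connectivity matrix: eta-squared
similarity between voxel connectivity profiles, the dominant gradient
from a Laplacian-eigenmaps decomposition, a third-order Bayesian trend
surface over voxel coordinates, the similarity-with-middle-section
(SMS) profile over five rostro-caudal sections, cortical
back-projection of the gradient extremes, and a bootstrap group
comparison of SMS profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.sparse.csgraph import connected_components

__all__ = [
    "eta_squared",
    "similarity_matrix",
    "laplacian_gradient",
    "trend_surface_fit",
    "sms_profile",
    "section_of_z",
    "backproject",
    "bootstrap_compare",
    "subject_sms",
]

#: Section index (1..5) for each LC z-level: 23-24 caudal (i=1,2),
#: 25-26 middle (i=3), 27-28 rostral (i=4,5).
_Z_TO_SECTION = {23: 1, 24: 2, 25: 3, 26: 3, 27: 4, 28: 5}

CAUDAL_SECTIONS = (1, 2)
MIDDLE_SECTION = 3
ROSTRAL_SECTIONS = (4, 5)


def section_of_z(z) -> np.ndarray:
    """Map integer z-coordinates (23..28) to section indices 1..5."""
    z = np.asarray(z)
    try:
        return np.vectorize(_Z_TO_SECTION.__getitem__)(z)
    except KeyError as e:
        raise ValueError(f"z-coordinate outside the LC convention 23..28: {e}")


def eta_squared(a, b) -> float:
    """Eta-squared similarity between two connectivity profiles.

    eta^2 = 1 - sum_i[(a_i-m_i)^2 + (b_i-m_i)^2] / sum_i[(a_i-M)^2 + (b_i-M)^2]

    with m_i the pointwise mean of the two profiles and M their grand
    mean. Equals 1 iff the profiles are identical; symmetric in its
    arguments. Raises on profiles shorter than 2, unequal lengths, or a
    zero denominator (both profiles constant and equal in mean).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("profiles must have length >= 2")
    m = (a + b) / 2.0
    grand = m.mean()
    num = float(((a - m) ** 2).sum() + ((b - m) ** 2).sum())
    den = float(((a - grand) ** 2).sum() + ((b - grand) ** 2).sum())
    if den == 0.0:
        raise ZeroDivisionError("total sum of squares is zero; eta-squared undefined")
    return 1.0 - num / den


def similarity_matrix(conn) -> np.ndarray:
    """Voxel x voxel eta-squared similarity of connectivity profiles.

    Vectorized over all pairs; entry (i, j) equals
    ``eta_squared(conn[i], conn[j])``. Symmetric with unit diagonal.
    """
    X = np.asarray(conn, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D voxels x parcels matrix with >= 2 parcels")
    n, p = X.shape
    # numerator: 0.5 * squared euclidean distance between rows
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
    num = 0.5 * np.maximum(d2, 0.0)
    # denominator: Q_i + Q_j - 2 p M_ij^2 with M_ij = (mean_i + mean_j)/2
    means = X.mean(axis=1)
    M = 0.5 * (means[:, None] + means[None, :])
    den = sq[:, None] + sq[None, :] - 2 * p * M**2
    if np.any(np.isclose(den, 0.0)):
        raise ZeroDivisionError("zero total sum of squares for some voxel pair")
    S = 1.0 - num / den
    np.fill_diagonal(S, 1.0)
    return (S + S.T) / 2.0


def _canonical_sign(values: np.ndarray, voxel_z) -> np.ndarray:
    """Fix the eigenvector sign so rostral sections average at least as
    high as caudal ones (gradients are sign-ambiguous)."""
    if voxel_z is None:
        # fall back: make the second half of nodes average higher
        half = values.size // 2
        if values[half:].mean() < values[:half].mean():
            return -values
        return values
    sec = section_of_z(voxel_z)
    rostral = values[np.isin(sec, ROSTRAL_SECTIONS)]
    caudal = values[np.isin(sec, CAUDAL_SECTIONS)]
    if rostral.size and caudal.size and rostral.mean() < caudal.mean():
        return -values
    return values


def laplacian_gradient(sim, voxel_z=None, n_components_tol: float = 1e-12) -> np.ndarray:
    """Dominant connectopic gradient by Laplacian eigenmaps.

    Uses the similarity matrix as graph affinity, forms the symmetric
    normalized Laplacian, and takes the generalized eigenvector of the
    smallest nonzero eigenvalue (the Fiedler direction of the random
    walk). Values are min-max rescaled to [0, 1] and the sign is
    canonicalized so the rostral mean is at least the caudal mean when
    ``voxel_z`` is supplied. Raises on a disconnected affinity graph,
    reporting the number of components.
    """
    W = np.asarray(sim, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("similarity matrix must be square")
    if np.any(W < -1e-12):
        raise ValueError("affinity matrix must be nonnegative")
    W = np.maximum((W + W.T) / 2.0, 0.0)
    A = W.copy()
    np.fill_diagonal(A, 0.0)
    n_comp, _ = connected_components((A > n_components_tol).astype(int), directed=False)
    if n_comp > 1:
        raise ValueError(f"affinity graph is disconnected ({n_comp} components)")
    d = W.sum(axis=1)
    d_isqrt = 1.0 / np.sqrt(d)
    L_sym = np.eye(len(W)) - (d_isqrt[:, None] * W) * d_isqrt[None, :]
    L_sym = (L_sym + L_sym.T) / 2.0
    evals, evecs = scipy.linalg.eigh(L_sym)
    # skip the trivial eigenvector (eigenvalue 0)
    idx = int(np.searchsorted(evals, 1e-10))
    u = evecs[:, idx]
    v = d_isqrt * u  # back to the generalized (random-walk) eigenvector
    v = _canonical_sign(v, voxel_z)
    vmin, vmax = v.min(), v.max()
    if vmax - vmin == 0:
        raise ValueError("degenerate gradient (constant eigenvector)")
    return (v - vmin) / (vmax - vmin)


@dataclass
class TrendSurfaceFit:
    """Posterior summary of the third-order spatial trend surface."""

    terms: tuple[str, ...]
    coef: np.ndarray  # posterior means, aligned with terms
    coef_sd: np.ndarray  # posterior SDs
    noise_sd: float
    prior_precision: float

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.terms, self.coef))


_TREND_TERMS = ("intercept", "x", "y", "z", "x2", "y2", "z2", "x3", "y3", "z3")


def trend_surface_fit(values, coords, prior_precision: float = 1e-8) -> TrendSurfaceFit:
    """Bayesian third-order trend surface over voxel coordinates.

    Basis: intercept plus x, y, z and their second and third powers
    (10 terms). Coordinates are standardized internally. The slopes
    carry a zero-mean isotropic Gaussian prior (ridge-equivalent with
    penalty ``prior_precision``); the intercept is unpenalized. In the
    weak-prior limit the posterior mean equals ordinary least squares;
    as the prior precision grows all slopes shrink to zero.
    """
    y = np.asarray(values, dtype=float)
    C = np.asarray(coords, dtype=float)
    if C.ndim != 2 or C.shape[1] != 3:
        raise ValueError("coords must be (n, 3)")
    if y.size < 11:
        raise ValueError("need at least 11 voxels for a 10-term basis")
    mu, sd = C.mean(axis=0), C.std(axis=0)
    sd[sd == 0] = 1.0
    Cs = (C - mu) / sd
    X = np.column_stack(
        [np.ones(len(y)), Cs, Cs**2, Cs**3]
    )
    if np.linalg.matrix_rank(np.unique(X, axis=0)) < X.shape[1]:
        raise ValueError("rank-deficient trend basis after deduplication")
    penalty = np.full(X.shape[1], prior_precision)
    penalty[0] = 0.0  # flat prior on the intercept
    A = X.T @ X + np.diag(penalty)
    coef = np.linalg.solve(A, X.T @ y)
    resid = y - X @ coef
    dof = max(len(y) - X.shape[1], 1)
    noise_var = float(resid @ resid) / dof
    cov = noise_var * np.linalg.inv(A)
    return TrendSurfaceFit(
        terms=_TREND_TERMS,
        coef=coef,
        coef_sd=np.sqrt(np.diag(cov)),
        noise_sd=float(np.sqrt(noise_var)),
        prior_precision=prior_precision,
    )


def sms_profile(gradient_values, voxel_z) -> pd.DataFrame:
    """Similarity with the middle section, over five LC sections.

    Section means S_i (i = 1..5) are computed on gradient values already
    scaled to [0, 1]; the raw statistic for the caudal and rostral
    sections is SMS_i = -|S_i - S_middle| and its normalized form is
    1 - |S_i - S_middle|, so 1 marks perfect similarity with the middle
    section and 0 the maximal possible dissimilarity on the unit scale.
    The middle section's trivial self-similarity is not reported.
    Raises if any section holds no voxels.
    """
    g = np.asarray(gradient_values, dtype=float)
    if np.any(g < -1e-9) or np.any(g > 1 + 1e-9):
        raise ValueError("gradient values must lie in [0, 1]")
    sec = section_of_z(voxel_z)
    means = {}
    for i in range(1, 6):
        sel = sec == i
        if not sel.any():
            raise ValueError(f"LC section {i} contains no voxels")
        means[i] = float(g[sel].mean())
    rows = []
    for i in (1, 2, 4, 5):
        diff = abs(means[i] - means[MIDDLE_SECTION])
        rows.append(
            {
                "section": i,
                "region": "caudal" if i in CAUDAL_SECTIONS else "rostral",
                "section_mean": means[i],
                "middle_mean": means[MIDDLE_SECTION],
                "sms_raw": -diff,
                "sms_normalized": 1.0 - diff,
            }
        )
    return pd.DataFrame(rows)


def subject_sms(conn, voxel_z) -> pd.DataFrame:
    """Full per-subject pipeline: similarity -> gradient -> SMS profile."""
    sim = similarity_matrix(conn)
    grad = laplacian_gradient(sim, voxel_z)
    return sms_profile(grad, voxel_z)


def backproject(conn, voxel_z, r_threshold: float = 0.15) -> pd.DataFrame:
    """Label cortical parcels by connectivity with the gradient extremes.

    For each parcel, the Pearson correlation is taken between its
    connectivity column (over voxels) and the membership pattern of each
    extreme region (caudal sections 1-2; rostral sections 4-5). A
    correlation at or above ``r_threshold`` (inclusive at the boundary)
    marks the parcel as connected to that extreme; parcels can be
    caudal-connected, rostral-connected, both, or neither.
    """
    X = np.asarray(conn, dtype=float)
    sec = section_of_z(voxel_z)
    out = []
    caudal_w = np.isin(sec, CAUDAL_SECTIONS).astype(float)
    rostral_w = np.isin(sec, ROSTRAL_SECTIONS).astype(float)

    def _corr(col, w):
        if col.std() == 0 or w.std() == 0:
            return 0.0
        return float(np.corrcoef(col, w)[0, 1])

    for j in range(X.shape[1]):
        rc = _corr(X[:, j], caudal_w)
        rr = _corr(X[:, j], rostral_w)
        caud = rc >= r_threshold
        rost = rr >= r_threshold
        label = (
            "both" if caud and rost else "caudal_connected" if caud else "rostral_connected" if rost else "neither"
        )
        out.append({"parcel": j, "r_caudal": rc, "r_rostral": rr, "label": label})
    return pd.DataFrame(out)


def bootstrap_compare(
    group_a_profiles: pd.DataFrame,
    group_b_profiles: pd.DataFrame,
    n_boot: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Percentile-bootstrap comparison of normalized SMS between groups.

    Inputs are per-subject SMS tables (columns ``subject_id``,
    ``section``, ``sms_normalized``). Subjects are resampled with
    replacement within each group; for every section the group-mean
    difference (A - B), its percentile 95% CI, and a two-sided p-value
    from CI inversion are reported. Swapping the groups flips every
    difference's sign.
    """
    if n_boot < 100:
        warnings.warn("fewer than 100 bootstrap iterations; estimates will be crude")
    rng = np.random.default_rng(seed)

    def _pivot(df):
        return df.pivot_table(index="subject_id", columns="section", values="sms_normalized")

    A = _pivot(group_a_profiles).to_numpy()
    B = _pivot(group_b_profiles).to_numpy()
    if len(A) < 2 or len(B) < 2:
        raise ValueError("need at least 2 subjects per group")
    sections = sorted(group_a_profiles["section"].unique())
    obs = A.mean(axis=0) - B.mean(axis=0)
    boots = np.empty((n_boot, len(sections)))
    for b in range(n_boot):
        ia = rng.integers(0, len(A), len(A))
        ib = rng.integers(0, len(B), len(B))
        boots[b] = A[ia].mean(axis=0) - B[ib].mean(axis=0)
    lo = np.percentile(boots, 2.5, axis=0)
    hi = np.percentile(boots, 97.5, axis=0)
    # two-sided p by CI inversion with an add-one guard
    p_pos = (np.sum(boots <= 0, axis=0) + 1) / (n_boot + 1)
    p_neg = (np.sum(boots >= 0, axis=0) + 1) / (n_boot + 1)
    p = np.minimum(1.0, 2 * np.minimum(p_pos, p_neg))
    return pd.DataFrame(
        {
            "section": sections,
            "diff": obs,
            "ci_low": lo,
            "ci_high": hi,
            "p": p,
        }
    )
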