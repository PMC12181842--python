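"""Synthetic multi-modal cohort generator.

Emulates the statistical structure the downstream stages assume: two
latent phenotype groups (body-first / brain-first) with baseline offsets
and divergent slopes on motor, cognitive and psychiatric scales, a
roughly two-fold conversion hazard for body-first prodromal subjects,
rostro-caudal locus-coeruleus gradient differences, asymmetric versus
symmetric striatal binding and DTI-ALPS values, and allele-frequency
differences between phenotypes on a SNP panel.

Fixtures start at the derived-quantity level (connectivity matrices,
count densities, ROI diffusivities); raw image volumes are never
simulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from socpd.scales import SCALES, clip_round
from socpd.phenotyping import HCReference

__all__ = [
    "CohortConfig",
    "generate_reference_controls",
    "generate_cohort",
    "generate_imaging",
    "generate_genotypes",
]


def _default_baseline_offsets() -> dict[str, float]:
    # Body-first minus brain-first at baseline, in healthy-control SD
    # units. Directions follow the worse motor, autonomic, psychiatric
    # and (mildly) cognitive status of the body-first group.
    return {
        "updrs1": 0.8,
        "updrs2": 0.5,
        "updrs3": 0.4,
        "gds": 0.5,
        "stai": 0.5,
        "moca": -0.2,
        "sdmt": -0.3,
        "hvlt_recall": -0.2,
        "lns": -0.2,
        "semantic_fluency": -0.2,
        "benton": -0.1,
    }


def _default_slope_diffs() -> dict[str, float]:
    # Body-first minus brain-first progression rates, raw units / year.
    return {
        "updrs2": 0.3,
        "updrs3": 0.5,
        "updrs4": 0.1,
        "moca": -0.4,
        "sdmt": -0.8,
        "gds": 0.15,
    }


#: Common progression in both phenotypes (raw units / year).
BASE_SLOPES = {
    "updrs1": 0.2,
    "updrs2": 0.3,
    "updrs3": 1.0,
    "updrs4": 0.1,
    "moca": -0.4,
    "sdmt": -1.0,
    "gds": 0.1,
}

#: Additive baseline shifts from the healthy-control mean, by cohort.
COHORT_SHIFTS = {
    "clinical": {
        "updrs1": 3.0,
        "updrs2": 4.0,
        "updrs3": 18.0,
        "updrs4": 0.5,
        "moca": -1.5,
        "gds": 0.5,
        "stai": 8.0,
    },
    "prodromal": {
        "updrs1": 2.0,
        "updrs2": 1.0,
        "updrs3": 2.0,
        "moca": -0.3,
        "gds": 0.5,
        "stai": 5.0,
    },
    "hc": {},
}

#: Marker-scale generating distributions by latent phenotype.
#: Body-first centres sit at the clinical body-first medians; the
#: brain-first group is by construction within the normal range, so its
#: spread is compressed relative to controls.
MARKER_DISTS = {
    "body_first": {"rbdsq": (6.5, 2.0), "scopa_aut": (13.0, 3.5)},
    "brain_first": {"rbdsq": (1.5, 1.2), "scopa_aut": (5.0, 2.0)},
}


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort.

    ``baseline_offsets`` are body-first minus brain-first baseline
    effects in healthy-control SD units; ``slope_diffs`` are extra
    progression in raw scale units per year; ``conversion_hr`` is the
    hazard ratio (body-first vs brain-first) of phenoconversion for
    prodromal subjects, applied to an exponential baseline hazard.
    """

    n_hc: int = 263
    n_prodromal: int = 500
    n_clinical: int = 500
    visit_times: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
    baseline_offsets: dict[str, float] = field(default_factory=_default_baseline_offsets)
    slope_diffs: dict[str, float] = field(default_factory=_default_slope_diffs)
    conversion_hr: float = 2.0
    baseline_conversion_rate: float = 0.06  # events / year, brain-first
    dropout_rate: float = 0.05  # per post-baseline visit, MCAR
    body_first_frac: float = 0.5
    noise_sd_frac: float = 0.35  # visit noise, fraction of HC SD
    intercept_sd_frac: float = 0.5  # subject random intercept, fraction of HC SD
    tremor_prob: dict[str, float] = field(
        default_factory=lambda: {"body_first": 0.45, "brain_first": 0.7}
    )
    tremor_flip_prob: float = 0.08  # visit-level observation noise on the flag
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hc, self.n_prodromal, self.n_clinical) < 0:
            raise ValueError("cohort sizes must be non-negative")
        times = tuple(float(t) for t in self.visit_times)
        if not times or times[0] != 0.0:
            raise ValueError("visit_times must start at 0")
        if any(b >= a for a, b in zip(times[1:], times[:-1])):
            raise ValueError("visit_times must be strictly increasing")
        if self.conversion_hr <= 0:
            raise ValueError("conversion_hr must be positive")
        self.visit_times = times


def _rng(seed, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def generate_reference_controls(config: CohortConfig):
    """Simulate the healthy-control sample and derive the reference table.

    Returns ``(HCReference, visit_table)``. Per-scale mean and SD are
    computed from the simulated draws (not copied from the generating
    parameters), mirroring how a control reference is built in practice.

    Raises ``ValueError`` if fewer than two controls are requested (the
    SD is then undefined).
    """
    if config.n_hc < 2:
        raise ValueError("need at least 2 healthy controls to estimate an SD")
    rng = _rng(config.seed, 0)
    n = config.n_hc
    rows = {"subject_id": [f"HC{i:04d}" for i in range(n)], "cohort": "hc", "time_years": 0.0}
    for name, sc in SCALES.items():
        rows[name] = clip_round(rng.normal(sc.hc_mean, sc.hc_sd, size=n), sc)
    table = pd.DataFrame(rows)
    stats = {
        name: (float(table[name].mean()), float(table[name].std(ddof=1)), n)
        for name in SCALES
    }
    ref = HCReference(stats)
    for name, (_, sd, _) in ref.stats.items():
        if sd == 0:
            warnings.warn(f"degenerate healthy-control reference for {name}: sd=0")
    return ref, table


def _subject_frame(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-subject latent attributes for the case cohorts."""
    n = config.n_prodromal + config.n_clinical
    cohort = np.array(["prodromal"] * config.n_prodromal + ["clinical"] * config.n_clinical)
    phenotype = np.where(
        rng.random(n) < config.body_first_frac, "body_first", "brain_first"
    )
    subjects = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "cohort": cohort,
            "true_phenotype": phenotype,
            "age": np.round(rng.normal(65, 8, n), 1),
            "sex": rng.integers(0, 2, n),  # 1 = male
            "education": np.round(np.clip(rng.normal(15, 3, n), 5, 24)),
            "disease_duration": np.where(
                cohort == "clinical", np.round(np.clip(rng.normal(1.5, 1.0, n), 0, None), 2), 0.0
            ),
        }
    )
    return subjects


def _conversion(config: CohortConfig, subjects: pd.DataFrame, rng: np.random.Generator):
    """Exponential time to PD diagnosis for prodromal subjects,
    censored at the last scheduled visit."""
    horizon = config.visit_times[-1]
    n = len(subjects)
    rate = np.full(n, config.baseline_conversion_rate)
    rate[subjects["true_phenotype"].to_numpy() == "body_first"] *= config.conversion_hr
    t = rng.exponential(1.0 / rate)
    prodromal = (subjects["cohort"] == "prodromal").to_numpy()
    event = prodromal & (t <= horizon)
    time = np.where(prodromal, np.minimum(t, horizon), 0.0)
    # clinical subjects enter already diagnosed
    event = np.where(prodromal, event, True)
    return event.astype(bool), np.round(time, 3)


def generate_cohort(config: CohortConfig, hc_ref: HCReference) -> pd.DataFrame:
    """Generate the long-format visit table for the case cohorts.

    One row per subject-visit, with all clinical scale scores, the
    resting-tremor flag, lateralized motor sums, covariates, conversion
    outcome, and the latent ``true_phenotype`` (generator-only column).
    Missingness (whole-visit dropout) is applied after generation,
    missing completely at random, never at baseline.
    """
    if not config.visit_times:
        raise ValueError("visit_times is empty")
    rng = _rng(config.seed, 1)
    subjects = _subject_frame(config, rng)
    n = len(subjects)
    times = np.asarray(config.visit_times)
    body = (subjects["true_phenotype"] == "body_first").to_numpy()

    event, ttime = _conversion(config, subjects, rng)
    subjects["converted_to_pd"] = event
    subjects["conversion_time"] = ttime

    # latent per-subject marker levels (fixed across visits up to noise)
    marker_level = {}
    for scale in ("rbdsq", "scopa_aut"):
        mb, sb = MARKER_DISTS["body_first"][scale]
        mn, sn = MARKER_DISTS["brain_first"][scale]
        marker_level[scale] = np.where(
            body, rng.normal(mb, sb, n), rng.normal(mn, sn, n)
        )

    tremor_latent = rng.random(n) < np.where(
        body, config.tremor_prob["body_first"], config.tremor_prob["brain_first"]
    )
    # lateralized motor burden: brain-first strongly one-sided
    dominant_right = rng.random(n) < 0.5
    base_lat = np.clip(rng.normal(5, 1.5, n), 0.5, None)
    asym = np.where(body, rng.normal(0.5, 0.3, n), rng.normal(4.0, 0.8, n))
    lat_r = base_lat + np.where(dominant_right, np.clip(asym, 0, None), 0)
    lat_l = base_lat + np.where(~dominant_right, np.clip(asym, 0, None), 0)

    intercepts = {
        name: rng.normal(0, config.intercept_sd_frac * sc.hc_sd, n)
        for name, sc in SCALES.items()
    }

    frames = []
    for t in times:
        row = subjects.copy()
        row["time_years"] = t
        for name, sc in SCALES.items():
            if name in ("rbdsq", "scopa_aut"):
                base = marker_level[name]
                drift = 0.0
            else:
                shift_c = np.array(
                    [COHORT_SHIFTS[c].get(name, 0.0) for c in subjects["cohort"]]
                )
                off = config.baseline_offsets.get(name, 0.0) * sc.hc_sd
                base = sc.hc_mean + shift_c + np.where(body, off, 0.0) + intercepts[name]
                slope = BASE_SLOPES.get(name, 0.0) + np.where(
                    body, config.slope_diffs.get(name, 0.0), 0.0
                )
                drift = slope * t
            noise = rng.normal(0, config.noise_sd_frac * sc.hc_sd, n)
            row[name] = clip_round(base + drift + noise, sc)
        flips = rng.random(n) < config.tremor_flip_prob
        row["resting_tremor_present"] = np.where(flips, ~tremor_latent, tremor_latent)
        row["lateralized_motor_right"] = np.round(lat_r + rng.normal(0, 0.3, n), 2)
        row["lateralized_motor_left"] = np.round(lat_l + rng.normal(0, 0.3, n), 2)
        frames.append(row)

    visits = pd.concat(frames, ignore_index=True)

    # MCAR whole-visit dropout after baseline
    post = visits["time_years"] > 0
    keep = ~post | (rng.random(len(visits)) >= config.dropout_rate)
    visits = visits.loc[keep].reset_index(drop=True)
    return visits.sort_values(["subject_id", "time_years"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# imaging fixtures
# ---------------------------------------------------------------------------

#: z-levels of the locus coeruleus mask (MNI integer convention).
LC_Z_LEVELS = (23, 24, 25, 26, 27, 28)

#: Planted latent gradient position per z-level, by phenotype. In the
#: body-first field the caudal levels sit close to the middle; in
#: brain-first the rostral levels do.
LATENT_GRADIENT = {
    "body_first": {23: 0.40, 24: 0.45, 25: 0.50, 26: 0.50, 27: 0.75, 28: 1.00},
    "brain_first": {23: 0.00, 24: 0.25, 25: 0.50, 26: 0.50, 27: 0.55, 28: 0.60},
}


@dataclass
class ImagingFixture:
    """Derived-quantity imaging inputs for one cohort."""

    lc_connectivity: dict  # subject_id -> (voxels x parcels array)
    lc_voxel_z: np.ndarray  # shared z-coordinate per voxel
    sbr_table: pd.DataFrame  # subject, hemisphere, region, striatal, occipital
    alps_table: pd.DataFrame  # subject, hemisphere, Dx_proj, Dx_assoc, Dy_proj, Dz_assoc


def generate_imaging(
    config: CohortConfig,
    phenotypes: pd.DataFrame,
    *,
    n_voxels_per_z: int = 5,
    n_parcels: int = 60,
    conn_noise: float = 0.10,
    sbr_asymmetry: float = 0.5,
    alps_less_affected: dict | None = None,
) -> ImagingFixture:
    """Generate LC connectivity, striatal count-density and ALPS fixtures.

    ``phenotypes`` must have columns ``subject_id`` and ``true_phenotype``
    (or ``phenotype``). Body-first fields are built so caudal sections'
    connectivity profiles resemble the middle section; brain-first
    striatal counts are more asymmetric between hemispheres; ALPS
    diffusivities give a higher less-affected-hemisphere index for
    brain-first subjects. With ``sbr_asymmetry=0`` left and right
    striatal counts are equal in expectation.
    """
    rng = _rng(config.seed, 2)
    col = "true_phenotype" if "true_phenotype" in phenotypes else "phenotype"
    ph = phenotypes.drop_duplicates("subject_id")[["subject_id", col]]
    if alps_less_affected is None:
        alps_less_affected = {"body_first": 1.38, "brain_first": 1.55}
    alps_more_affected = 1.28

    voxel_z = np.repeat(LC_Z_LEVELS, n_voxels_per_z)
    conn = {}
    sbr_rows, alps_rows = [], []
    for subject_id, pheno in ph.itertuples(index=False):
        latent = np.array([LATENT_GRADIENT[pheno][z] for z in voxel_z])
        latent = latent + rng.normal(0, 0.02, latent.size)
        u0 = rng.normal(0, 1, n_parcels)
        u1 = rng.normal(0, 1, n_parcels)
        u1 /= np.linalg.norm(u1) / np.sqrt(n_parcels)
        mat = u0[None, :] + latent[:, None] * u1[None, :]
        mat += rng.normal(0, conn_noise, mat.shape)
        conn[subject_id] = mat

        occ = rng.normal(1.0, 0.05)
        for region, base in (("putamen", 2.2), ("caudate", 2.6)):
            if pheno == "brain_first":
                less = base + sbr_asymmetry + rng.normal(0, 0.15)
                more = base - 0.1 + rng.normal(0, 0.15)
            else:
                less = base - 0.05 + rng.normal(0, 0.15)
                more = base - 0.1 + rng.normal(0, 0.15)
            for hemi, striatal in (("less_affected", less), ("more_affected", more)):
                sbr_rows.append(
                    {
                        "subject_id": subject_id,
                        "hemisphere": hemi,
                        "region": region,
                        "striatal_counts": max(striatal, 0.05),
                        "occipital_counts": max(occ, 0.05),
                    }
                )

        for hemi, target in (
            ("less_affected", alps_less_affected[pheno]),
            ("more_affected", alps_more_affected),
        ):
            d = 0.8e-3
            jit = rng.normal(1.0, 0.02, 4)
            alps_rows.append(
                {
                    "subject_id": subject_id,
                    "hemisphere": hemi,
                    "Dx_proj": target * d * jit[0],
                    "Dx_assoc": target * d * jit[1],
                    "Dy_proj": d * jit[2],
                    "Dz_assoc": d * jit[3],
                }
            )

    return ImagingFixture(
        lc_connectivity=conn,
        lc_voxel_z=voxel_z,
        sbr_table=pd.DataFrame(sbr_rows),
        alps_table=pd.DataFrame(alps_rows),
    )


# ---------------------------------------------------------------------------
# genotype fixtures
# ---------------------------------------------------------------------------

def generate_genotypes(
    config: CohortConfig,
    phenotypes: pd.DataFrame,
    *,
    n_snps: int = 123,
    n_causal: int = 5,
    causal_or: float = 2.0,
    missing_rate: float = 0.02,
) -> tuple[pd.DataFrame, list[str]]:
    """Generate a subjects x SNPs dosage matrix (0/1/2, NaN missing).

    Most SNPs are drawn from Hardy-Weinberg proportions independent of
    phenotype; ``n_causal`` SNPs have genotype distributions tilted by
    ``causal_or`` per risk allele in body-first subjects. Returns the
    dosage DataFrame (index = subject_id) and the list of causal SNP
    names.
    """
    rng = _rng(config.seed, 3)
    col = "true_phenotype" if "true_phenotype" in phenotypes else "phenotype"
    ph = phenotypes.drop_duplicates("subject_id")[["subject_id", col]]
    body = (ph[col] == "body_first").to_numpy()
    n = len(ph)
    mafs = rng.uniform(0.1, 0.4, n_snps)
    snps = [f"rs{100000 + i}" for i in range(n_snps)]
    causal = sorted(rng.choice(n_snps, size=n_causal, replace=False))
    geno = np.empty((n, n_snps))
    for j, maf in enumerate(mafs):
        p = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
        if j in causal:
            w = p * causal_or ** np.arange(3)
            p_body = w / w.sum()
        else:
            p_body = p
        g = np.where(
            body,
            rng.choice(3, size=n, p=p_body),
            rng.choice(3, size=n, p=p),
        )
        geno[:, j] = g
    mask = rng.random(geno.shape) < missing_rate
    geno[mask] = np.nan
    df = pd.DataFrame(geno, index=ph["subject_id"].to_numpy(), columns=snps)
    df.index.name = "subject_id"
    return df, [snps[j] for j in causal]


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    """Return a copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
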