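"""End-to-end orchestration over the synthetic cohort.

``run_pipeline`` generates a cohort, classifies phenotypes, computes
imaging indices and locus-coeruleus SMS profiles, fits the longitudinal
and survival models, runs the SNP association with permutation FDR, and
trains the latent-phenotyping VAE. Stages exchange data through flat
files (CSV/JSON) written to the output directory; a manifest records
the configuration hash, the per-module seeds, and a SHA-256 checksum of
every emitted file, so that two runs with the same configuration and
seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from socpd import synth
from socpd.synth import CohortConfig, generate_reference_controls, generate_cohort
from socpd.phenotyping import classify_table, stability_analysis, SEVERITY_ORDERS
from socpd.imaging import add_sbr, add_alps
from socpd.lc_gradient import subject_sms, bootstrap_compare
from socpd.models import fit_trajectory, fit_cox, dementia_endpoint, fdr_adjust, mediate
from socpd.genetics import qc_filter, associate_phenotype, permutation_fdr
from socpd.vae import VAEConfig, build_feature_table, train_vae, embed_and_compare

logger = logging.getLogger("socpd")

__all__ = ["RunConfig", "run_pipeline"]

TRAJECTORY_OUTCOMES = ("updrs2", "updrs3", "moca", "gds")


@dataclass
class RunConfig:
    """Master configuration: one seed fans out to per-module seeds."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    outdir: str = "results/pipeline"
    run_imaging: bool = True
    run_genetics: bool = True
    run_vae: bool = True
    n_boot_sms: int = 1000
    # With m SNPs the smallest attainable permutation p is 1/(n_perm+1);
    # BH at q=0.05 needs that below 0.05/m, so n_perm must exceed
    # 20*m - 1 (2500 covers panels up to 125 SNPs).
    n_perm: int = 2500
    vae_epochs: int = 300

    def module_seed(self, stream: int) -> int:
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        return int(ss.generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["visit_times"] = list(d["cohort"]["visit_times"])
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _baseline_table(visits: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Cohort-characteristics comparison between phenotypes at baseline.

    Continuous scales: Wilcoxon rank-sum (Mann-Whitney U); binary
    variables: chi-squared. One row per variable per cohort.
    """
    base = visits[visits["time_years"] == 0].merge(
        labels[labels["time_years"] == 0][["subject_id", "soc"]], on="subject_id"
    )
    rows = []
    from socpd.scales import SCALES

    for cohort_name, dfc in base.groupby("cohort"):
        a = dfc[dfc["soc"] == "body_first"]
        b = dfc[dfc["soc"] == "brain_first"]
        if len(a) < 2 or len(b) < 2:
            continue
        for scale in list(SCALES) + ["age", "education"]:
            u, p = scipy.stats.mannwhitneyu(a[scale], b[scale], alternative="two-sided")
            rows.append(
                {
                    "cohort": cohort_name,
                    "variable": scale,
                    "body_first_median": float(a[scale].median()),
                    "brain_first_median": float(b[scale].median()),
                    "test": "mannwhitney",
                    "p": float(p),
                }
            )
        for flag in ("sex", "resting_tremor_present"):
            tab = pd.crosstab(dfc["soc"], dfc[flag])
            if tab.shape == (2, 2):
                chi2, p, _, _ = scipy.stats.chi2_contingency(tab)
                rows.append(
                    {
                        "cohort": cohort_name,
                        "variable": flag,
                        "body_first_median": float(a[flag].mean()),
                        "brain_first_median": float(b[flag].mean()),
                        "test": "chi2",
                        "p": float(p),
                    }
                )
    out = pd.DataFrame(rows)
    adj, rej = fdr_adjust(out["p"].to_numpy())
    out["p_fdr"] = adj
    out["significant"] = rej
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run every enabled stage and return the report manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.module_seed(0))
    files: dict[str, Path] = {}

    logger.info("stage 1/7: synthetic cohort")
    try:
        hc_ref, hc_table = generate_reference_controls(cohort_cfg)
        visits = generate_cohort(cohort_cfg, hc_ref)
    except Exception as e:
        raise RuntimeError(f"stage synth_cohort failed: {e}") from e
    _write_csv(hc_ref.to_frame(), out / "hc_reference.csv")
    _write_csv(visits, out / "visits.csv")
    files["hc_reference"] = out / "hc_reference.csv"
    files["visits"] = out / "visits.csv"

    logger.info("stage 2/7: phenotype classification and stability")
    labels = classify_table(visits, hc_ref, mode="full")
    _write_csv(labels, out / "labels.csv")
    files["labels"] = out / "labels.csv"
    stab_frames = []
    for system in ("soc", "cognition", "motor"):
        stab = stability_analysis(labels, SEVERITY_ORDERS[system], label_col=system)
        stab.insert(0, "system", system)
        stab_frames.append(stab)
    stability = pd.concat(stab_frames, ignore_index=True)
    _write_csv(stability, out / "stability.csv")
    files["stability"] = out / "stability.csv"

    baseline = _baseline_table(visits, labels)
    _write_csv(baseline, out / "baseline_table.csv")
    files["baseline_table"] = out / "baseline_table.csv"

    subj_labels = (
        labels[labels["time_years"] == 0][["subject_id", "soc"]]
        .rename(columns={"soc": "phenotype"})
    )
    model_visits = visits.merge(subj_labels, on="subject_id")

    logger.info("stage 3/7: trajectory mixed models")
    traj = []
    for cohort_name, dfc in model_visits.groupby("cohort"):
        for outcome in TRAJECTORY_OUTCOMES:
            try:
                res = fit_trajectory(dfc, outcome, comparison_level="body_first")
            except (ValueError, RuntimeError) as e:
                raise RuntimeError(
                    f"stage longitudinal_models failed on {cohort_name}/{outcome}: {e}"
                ) from e
            res.insert(0, "cohort", cohort_name)
            traj.append(res)
    trajectories = pd.concat(traj, ignore_index=True)
    inter = trajectories["term"] == "group:time"
    adj = np.full(len(trajectories), np.nan)
    adj[inter.to_numpy()], rej = fdr_adjust(trajectories.loc[inter, "p"].to_numpy())
    trajectories["p_fdr"] = adj
    _write_csv(trajectories, out / "trajectories.csv")
    files["trajectories"] = out / "trajectories.csv"

    logger.info("stage 4/7: survival models")
    surv_rows = []
    prod = model_visits[model_visits["cohort"] == "prodromal"]
    conv = prod[prod["time_years"] == 0][
        ["subject_id", "phenotype", "age", "sex", "education",
         "converted_to_pd", "conversion_time"]
    ].rename(columns={"conversion_time": "duration", "converted_to_pd": "event"})
    conv["event"] = conv["event"].astype(int)

    clin = model_visits[model_visits["cohort"] == "clinical"]
    dem = dementia_endpoint(clin).merge(
        clin[clin["time_years"] == 0][["subject_id", "phenotype", "age", "sex", "education"]],
        on="subject_id",
    )
    for endpoint, table in (("pd_conversion", conv), ("dementia_moca_below_21", dem)):
        try:
            row = fit_cox(table, comparison_level="body_first")
            row["note"] = ""
        except ValueError as e:
            # An endpoint can be inestimable at small cohort sizes (no
            # events, or none in one group); record it rather than fail.
            logger.warning("survival endpoint %s not estimable: %s", endpoint, e)
            row = {
                "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                "n": int(len(table)), "n_events": int(table["event"].sum()),
                "group_reference": "brain_first", "group_comparison": "body_first",
                "ph_ok": True, "note": f"not estimable: {e}",
            }
        row["endpoint"] = endpoint
        surv_rows.append(row)
    survival = pd.DataFrame(
        [{k: v for k, v in r.items() if k != "schoenfeld_p"} for r in surv_rows]
    )
    _write_csv(survival, out / "survival.csv")
    files["survival"] = out / "survival.csv"

    mediation_out = None
    if config.run_imaging:
        logger.info("stage 5/7: imaging indices and LC gradients")
        try:
            imaging_cfg = dataclasses.replace(cohort_cfg, seed=config.module_seed(1))
            fix = synth.generate_imaging(imaging_cfg, subj_labels.rename(columns={"phenotype": "true_phenotype"}))
        except Exception as e:
            raise RuntimeError(f"stage imaging failed: {e}") from e
        sbr = add_sbr(fix.sbr_table)
        alps = add_alps(fix.alps_table)
        _write_csv(sbr, out / "sbr.csv")
        _write_csv(alps, out / "alps.csv")
        files["sbr"] = out / "sbr.csv"
        files["alps"] = out / "alps.csv"

        sms_frames = []
        for sid, conn in fix.lc_connectivity.items():
            prof = subject_sms(conn, fix.lc_voxel_z)
            prof.insert(0, "subject_id", sid)
            sms_frames.append(prof)
        sms = pd.concat(sms_frames, ignore_index=True)
        sms = sms.merge(subj_labels, on="subject_id")
        _write_csv(sms, out / "sms.csv")
        files["sms"] = out / "sms.csv"

        comp = bootstrap_compare(
            sms[sms["phenotype"] == "body_first"],
            sms[sms["phenotype"] == "brain_first"],
            n_boot=config.n_boot_sms,
            seed=config.module_seed(2),
        )
        _write_csv(comp, out / "sms_group_comparison.csv")
        files["sms_group_comparison"] = out / "sms_group_comparison.csv"

        # glymphatic mediation: phenotype -> less-affected ALPS -> motor burden
        med_df = (
            alps[alps["hemisphere"] == "less_affected"][["subject_id", "alps_index"]]
            .merge(
                model_visits[model_visits["time_years"] == 0][
                    ["subject_id", "phenotype", "updrs3", "age", "sex"]
                ],
                on="subject_id",
            )
        )
        med_df["exposure"] = (med_df["phenotype"] == "body_first").astype(float)
        med = mediate(
            med_df,
            exposure="exposure",
            mediator="alps_index",
            outcome="updrs3",
            covariates=("age", "sex"),
            n_boot=max(config.n_boot_sms, 500),
            seed=config.module_seed(3),
        )
        mediation_out = {
            "indirect": med.indirect,
            "direct": med.direct,
            "total": med.total,
            "proportion_mediated_pct": 100.0 * med.proportion_mediated,
            "p": med.p,
        }
        (out / "mediation.json").write_text(json.dumps(mediation_out, indent=2, sort_keys=True))
        files["mediation"] = out / "mediation.json"

    genetics_out = {}
    risk_snps = None
    genotypes = None
    if config.run_genetics:
        logger.info("stage 6/7: genetics")
        try:
            gen_cfg = dataclasses.replace(cohort_cfg, seed=config.module_seed(4))
            genotypes, risk_snps = synth.generate_genotypes(gen_cfg, subj_labels.rename(columns={"phenotype": "true_phenotype"}))
            geno_qc, qc_report = qc_filter(genotypes)
            lab = subj_labels.set_index("subject_id")["phenotype"].map(
                {"body_first": 1, "brain_first": 0}
            )
            covs = (
                model_visits[model_visits["time_years"] == 0]
                .set_index("subject_id")[["age", "sex"]]
            )
            assoc = associate_phenotype(geno_qc, lab, covs)
            assoc_perm = permutation_fdr(
                assoc, geno_qc, lab, covs,
                n_perm=config.n_perm, seed=config.module_seed(5),
            )
        except Exception as e:
            raise RuntimeError(f"stage genetics failed: {e}") from e
        (out / "qc_report.json").write_text(json.dumps(qc_report.to_dict(), indent=2, sort_keys=True))
        _write_csv(assoc_perm, out / "association.csv")
        files["qc_report"] = out / "qc_report.json"
        files["association"] = out / "association.csv"
        genetics_out = {
            "n_significant": int(assoc_perm["significant"].sum()),
            "n_snps_tested": int(len(assoc_perm)),
        }

    vae_out = {}
    if config.run_vae:
        logger.info("stage 7/7: latent phenotyping VAE")
        try:
            alps_for_feat = add_alps(fix.alps_table) if config.run_imaging else None
            if genotypes is None:
                # The risk-dosage feature needs the genotype fixture even
                # when the association stage is disabled; the same seed
                # stream keeps the embedding identical either way.
                gen_cfg = dataclasses.replace(cohort_cfg, seed=config.module_seed(4))
                genotypes, risk_snps = synth.generate_genotypes(
                    gen_cfg, subj_labels.rename(columns={"phenotype": "true_phenotype"})
                )
            feats = build_feature_table(
                visits,
                labels=subj_labels,
                alps=alps_for_feat,
                genotypes=genotypes,
                risk_snps=risk_snps,
            )
            vcfg = VAEConfig(epochs=config.vae_epochs, seed=config.module_seed(6))
            model = train_vae(feats, vcfg)
            lab = subj_labels.set_index("subject_id")["phenotype"]
            emb, tests = embed_and_compare(model, feats, lab)
        except Exception as e:
            raise RuntimeError(f"stage latent_phenotyping failed: {e}") from e
        _write_csv(emb.reset_index(), out / "embedding.csv")
        _write_csv(model.curve, out / "training_curve.csv")
        _write_csv(tests, out / "latent_tests.csv")
        files["embedding"] = out / "embedding.csv"
        files["training_curve"] = out / "training_curve.csv"
        files["latent_tests"] = out / "latent_tests.csv"
        vae_out = {"tests": tests.to_dict("records")}

    # hash the scientific configuration only: the output location must
    # not change the config identity
    hashed = {k: v for k, v in config.to_dict().items() if k != "outdir"}
    config_json = json.dumps(hashed, sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "seeds": {f"stream_{i}": config.module_seed(i) for i in range(7)},
        "checksums": {name: _sha256(path) for name, path in sorted(files.items())},
        "mediation": mediation_out,
        "genetics": genetics_out,
        "latent": vae_out,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
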