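import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from socpd.genetics import (
    associate_phenotype,
    hwe_test,
    permutation_fdr,
    progression_by_genotype,
    qc_filter,
)


def hwe_oracle(n_AA, n_Aa, n_aa):
    n = n_AA + n_Aa + n_aa
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1 - p
    exp = [n * p * p, 2 * n * p * q, n * q * q]
    chi2 = sum((o - e) ** 2 / e for o, e in zip((n_AA, n_Aa, n_aa), exp))
    return chi2, scipy.stats.chi2.sf(chi2, 1)


class TestHWE:
    def test_perfect_hwe_counts(self):
        chi2, p = hwe_test(25, 50, 25)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_extreme_violation(self):
        chi2, p = hwe_test(50, 0, 50)
        assert chi2 == pytest.approx(100.0)
        assert p < 1e-20

    def test_matches_oracle_random_counts(self, rng):
        for _ in range(200):
            counts = rng.integers(0, 200, 3)
            if counts.sum() == 0:
                continue
            n_AA, n_Aa, n_aa = (int(c) for c in counts)
            p_hat = (2 * n_AA + n_Aa) / (2 * counts.sum())
            if p_hat in (0.0, 1.0):
                continue
            chi2, p = hwe_test(n_AA, n_Aa, n_aa)
            c_o, p_o = hwe_oracle(n_AA, n_Aa, n_aa)
            assert chi2 == pytest.approx(c_o, abs=1e-10)
            assert p == pytest.approx(p_o, abs=1e-10)

    def test_monomorphic_convention(self):
        assert hwe_test(100, 0, 0) == (0.0, 1.0)
        assert hwe_test(0, 0, 50) == (0.0, 1.0)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_test(-1, 2, 3)
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)


def constructed_panel():
    """10 subjects x 20 SNPs with exactly one removable entity per rule."""
    rng = np.random.default_rng(11)
    n, m = 10, 20
    geno = rng.choice([0.0, 1.0, 2.0], size=(n, m), p=[0.25, 0.5, 0.25])
    cols = [f"rs{i}" for i in range(m)]
    idx = [f"sub{i}" for i in range(n)]
    df = pd.DataFrame(geno, index=idx, columns=cols)
    df.iloc[0, :2] = np.nan  # subject sub0: 2/20 = 10% missing (> 5%)
    df.loc[df.index[1:][:2], "rs5"] = np.nan  # among remaining 9 subjects:
    # rs5 call rate 7/9 = 77.8% < 85%
    return df


class TestQC:
    def test_cascade_removes_exactly_the_planted_entities(self):
        df = constructed_panel()
        # give rs7 a gross HWE violation among the 9 surviving subjects
        df.loc[df.index[1:], "rs7"] = [0, 0, 0, 0, 2, 2, 2, 2, 0]
        g, report = qc_filter(df)
        assert report.subjects_removed_missing == ["sub0"]
        assert report.snps_removed_callrate == ["rs5"]
        assert report.snps_removed_hwe == ["rs7"]
        assert g.shape == (9, 18)

    def test_idempotent(self):
        df = constructed_panel()
        g1, _ = qc_filter(df)
        g2, r2 = qc_filter(g1)
        pd.testing.assert_frame_equal(g1, g2)
        assert not r2.subjects_removed_missing
        assert not r2.snps_removed_callrate and not r2.snps_removed_hwe

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            qc_filter(pd.DataFrame())

    def test_report_serializes(self):
        import json

        _, report = qc_filter(constructed_panel())
        json.dumps(report.to_dict())


def planted_association(n=500, beta=1.2, seed=2):
    rng = np.random.default_rng(seed)
    maf = 0.3
    g_causal = rng.choice(3, n, p=[(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    g_null = rng.choice(3, (n, 8), p=[(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    age = rng.normal(65, 8, n)
    sex = rng.integers(0, 2, n)
    logit = -0.8 + beta * g_causal
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    geno = pd.DataFrame(
        np.column_stack([g_causal, g_null]).astype(float),
        columns=["rs_causal"] + [f"rs_null{i}" for i in range(8)],
        index=[f"s{i}" for i in range(n)],
    )
    labels = pd.Series(y, index=geno.index)
    covs = pd.DataFrame({"age": age, "sex": sex}, index=geno.index)
    return geno, labels, covs


class TestAssociation:
    def test_recovers_planted_effect(self):
        geno, labels, covs = planted_association()
        out = associate_phenotype(geno, labels, covs).set_index("snp")
        assert out.loc["rs_causal", "beta"] == pytest.approx(1.2, abs=0.4)
        assert out.loc["rs_causal", "p"] < 1e-6
        assert out.loc["rs_causal", "p"] == out["p"].min()

    def test_constant_snp_excluded_with_warning(self):
        geno, labels, covs = planted_association(n=100)
        geno["rs_const"] = 1.0
        with pytest.warns(UserWarning, match="constant dosage"):
            out = associate_phenotype(geno, labels, covs)
        assert "rs_const" not in set(out["snp"])

    def test_nonbinary_labels_raise(self):
        geno, labels, covs = planted_association(n=50)
        with pytest.raises(ValueError):
            associate_phenotype(geno, labels + 1, covs)

    def test_separation_falls_back_flagged(self):
        rng = np.random.default_rng(5)
        n = 60
        g = rng.choice([0.0, 1.0, 2.0], n)
        y = (g > 0).astype(float)  # perfect separation by carrier status
        geno = pd.DataFrame({"rs_sep": g}, index=[f"s{i}" for i in range(n)])
        labels = pd.Series(y, index=geno.index)
        out = associate_phenotype(geno, labels)
        assert bool(out.iloc[0]["separation"])
        assert np.isfinite(out.iloc[0]["se"])


class TestPermutationFDR:
    def test_causal_snp_significant_nulls_not(self):
        geno, labels, covs = planted_association(n=600, beta=1.4, seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assoc = associate_phenotype(geno, labels, covs)
            out = permutation_fdr(assoc, geno, labels, covs, n_perm=500, seed=0)
        sig = set(out[out["significant"]]["snp"])
        assert sig == {"rs_causal"}

    def test_p_floor(self):
        geno, labels, covs = planted_association(n=400, beta=1.5, seed=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assoc = associate_phenotype(geno, labels, covs)
            out = permutation_fdr(assoc, geno, labels, covs, n_perm=200, seed=0)
        assert out["p_perm"].min() >= 1.0 / 201.0

    def test_maxt_variant(self):
        geno, labels, covs = planted_association(n=500, beta=1.4, seed=7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assoc = associate_phenotype(geno, labels, covs)
            out = permutation_fdr(assoc, geno, labels, covs, n_perm=300, seed=0,
                                  method="maxt")
        assert "p_maxt" in out.columns
        assert out.set_index("snp").loc["rs_causal", "significant"]

    def test_too_few_permutations_raise(self):
        geno, labels, covs = planted_association(n=100)
        assoc = associate_phenotype(geno, labels, covs)
        with pytest.raises(ValueError):
            permutation_fdr(assoc, geno, labels, covs, n_perm=50)

    def test_deterministic_given_seed(self):
        geno, labels, covs = planted_association(n=200, seed=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assoc = associate_phenotype(geno, labels, covs)
            a = permutation_fdr(assoc, geno, labels, covs, n_perm=150, seed=3)
            b = permutation_fdr(assoc, geno, labels, covs, n_perm=150, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestProgressionByGenotype:
    def test_requires_two_groups(self, visits):
        subj = visits["subject_id"].unique()
        groups = pd.Series("carrier", index=subj)
        with pytest.raises(ValueError):
            progression_by_genotype(visits, groups, "updrs3")

    def test_runs_on_cohort(self, visits):
        subj = visits["subject_id"].unique()
        rng = np.random.default_rng(0)
        groups = pd.Series(
            np.where(rng.random(len(subj)) < 0.5, "carrier", "non_carrier"), index=subj
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = progression_by_genotype(visits, groups, "updrs3")
        assert "group:time" in set(out["term"])
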