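import numpy as np
import pandas as pd
import pytest

from socpd.lc_gradient import (
    backproject,
    bootstrap_compare,
    eta_squared,
    laplacian_gradient,
    section_of_z,
    similarity_matrix,
    sms_profile,
    subject_sms,
    trend_surface_fit,
)
from tests.conftest import random_connected_affinity


def eta_squared_oracle(a, b):
    """Literal transcription of the eta-squared definition."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    m = (a + b) / 2
    M = m.mean()
    num = sum((a[i] - m[i]) ** 2 + (b[i] - m[i]) ** 2 for i in range(len(a)))
    den = sum((a[i] - M) ** 2 + (b[i] - M) ** 2 for i in range(len(a)))
    return 1 - num / den


class TestEtaSquared:
    def test_identical_profiles_give_one(self, rng):
        a = rng.normal(size=10)
        assert eta_squared(a, a) == 1.0

    def test_known_values(self):
        assert eta_squared([1, 0], [0, 1]) == pytest.approx(0.0)
        assert eta_squared([2, 0], [0, 0]) == pytest.approx(1.0 / 3.0)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=8)
        assert eta_squared(a, b) == pytest.approx(eta_squared(b, a))

    def test_matches_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(2, 12)
            a, b = rng.normal(size=n), rng.normal(size=n)
            assert eta_squared(a, b) == pytest.approx(eta_squared_oracle(a, b), abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            eta_squared([1.0], [2.0])
        with pytest.raises(ValueError):
            eta_squared([1, 2, 3], [1, 2])
        with pytest.raises(ZeroDivisionError):
            eta_squared([1.0, 1.0], [1.0, 1.0])


class TestSimilarityMatrix:
    def test_matches_pairwise_eta(self, rng):
        X = rng.normal(size=(7, 9))
        S = similarity_matrix(X)
        for i in range(7):
            for j in range(7):
                if i == j:
                    assert S[i, j] == 1.0
                else:
                    assert S[i, j] == pytest.approx(eta_squared(X[i], X[j]), abs=1e-10)

    def test_symmetric(self, rng):
        S = similarity_matrix(rng.normal(size=(6, 5)))
        assert np.allclose(S, S.T)

    def test_rejects_1d(self):
        with pytest.raises(ValueError):
            similarity_matrix(np.arange(5.0))


class TestLaplacianGradient:
    def _oracle(self, W):
        """Dense generalized eigenproblem L v = lam D v, smallest nonzero."""
        import scipy.linalg

        W = np.asarray(W, float)
        A = W.copy()
        np.fill_diagonal(A, 0.0)
        D = np.diag(W.sum(axis=1))
        L = D - W
        evals, evecs = scipy.linalg.eigh(L, D)
        idx = int(np.searchsorted(evals, 1e-10))
        v = evecs[:, idx]
        return (v - v.min()) / (v.max() - v.min())

    def test_matches_dense_oracle_up_to_sign(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 31))
            W = random_connected_affinity(rng, n)
            g = laplacian_gradient(W)
            o = self._oracle(W)
            err = min(np.max(np.abs(g - o)), np.max(np.abs(g - (1 - o))))
            assert err < 1e-8

    def test_path_graph_monotone(self):
        n = 12
        W = np.zeros((n, n))
        for i in range(n - 1):
            W[i, i + 1] = W[i + 1, i] = 1.0
        g = laplacian_gradient(W)
        d = np.diff(g)
        assert np.all(d > 0) or np.all(d < 0)

    def test_range_and_extremes(self, rng):
        W = random_connected_affinity(rng, 15)
        g = laplacian_gradient(W)
        assert g.min() == 0.0 and g.max() == 1.0

    def test_disconnected_raises(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            laplacian_gradient(W)

    def test_sign_canonicalization_rostral_high(self, rng):
        W = random_connected_affinity(rng, 12)
        z = np.repeat([23, 24, 25, 26, 27, 28], 2)
        g = laplacian_gradient(W, voxel_z=z)
        sec = section_of_z(z)
        assert g[np.isin(sec, (4, 5))].mean() >= g[np.isin(sec, (1, 2))].mean()


class TestTrendSurface:
    def test_weak_prior_equals_ols(self, rng):
        C = rng.normal(size=(60, 3))
        y = rng.normal(size=60)
        fit = trend_surface_fit(y, C, prior_precision=1e-10)
        mu, sd = C.mean(axis=0), C.std(axis=0)
        Cs = (C - mu) / sd
        X = np.column_stack([np.ones(60), Cs, Cs**2, Cs**3])
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(fit.coef, ols, atol=1e-6)

    def test_strong_prior_shrinks_slopes(self, rng):
        C = rng.normal(size=(50, 3))
        y = C[:, 0] + rng.normal(size=50)
        fit = trend_surface_fit(y, C, prior_precision=1e8)
        assert np.max(np.abs(fit.coef[1:])) < 1e-4
        assert fit.coef[0] == pytest.approx(y.mean(), abs=1e-6)

    def test_needs_11_voxels(self, rng):
        with pytest.raises(ValueError):
            trend_surface_fit(rng.normal(size=10), rng.normal(size=(10, 3)))


class TestSMS:
    def test_worked_profile(self):
        z = [23, 24, 25, 26, 27, 28]
        g = [0.1, 0.3, 0.5, 0.5, 0.7, 0.9]  # section means 0.1 0.3 0.5 0.7 0.9
        prof = sms_profile(g, z)
        assert list(prof["section"]) == [1, 2, 4, 5]
        assert list(prof["sms_normalized"]) == pytest.approx([0.6, 0.8, 0.8, 0.6])
        assert list(prof["sms_raw"]) == pytest.approx([-0.4, -0.2, -0.2, -0.4])

    def test_normalized_in_unit_interval(self, rng):
        z = np.repeat([23, 24, 25, 26, 27, 28], 4)
        g = rng.random(z.size)
        prof = sms_profile(g, z)
        assert ((prof["sms_normalized"] >= 0) & (prof["sms_normalized"] <= 1)).all()

    def test_equals_one_iff_matches_middle(self):
        z = [23, 24, 25, 26, 27, 28]
        g = [0.5, 0.2, 0.5, 0.5, 0.5, 0.9]
        prof = sms_profile(g, z).set_index("section")
        assert prof.loc[1, "sms_normalized"] == 1.0
        assert prof.loc[4, "sms_normalized"] == 1.0
        assert prof.loc[2, "sms_normalized"] < 1.0
        assert prof.loc[5, "sms_normalized"] < 1.0

    def test_empty_section_raises(self):
        with pytest.raises(ValueError, match="section"):
            sms_profile([0.1, 0.9], [23, 28])

    def test_out_of_range_gradient_raises(self):
        z = [23, 24, 25, 26, 27, 28]
        with pytest.raises(ValueError):
            sms_profile([0.1, 0.3, 0.5, 0.5, 0.7, 1.5], z)

    def test_bad_z_raises(self):
        with pytest.raises(ValueError):
            section_of_z([22])


class TestBackproject:
    def test_threshold_inclusive_and_labels(self):
        z = np.repeat([23, 24, 25, 26, 27, 28], 2)
        caudal = np.isin(section_of_z(z), (1, 2)).astype(float)
        rostral = np.isin(section_of_z(z), (4, 5)).astype(float)
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 1, len(z))
        conn = np.column_stack([caudal, rostral, caudal + rostral, noise])
        out = backproject(conn, z, r_threshold=0.15)
        assert out.loc[0, "label"] == "caudal_connected"
        assert out.loc[1, "label"] == "rostral_connected"
        assert out.loc[0, "r_caudal"] >= 0.15

    def test_constant_column_is_neither(self):
        z = np.repeat([23, 24, 25, 26, 27, 28], 2)
        conn = np.ones((len(z), 2))
        out = backproject(conn, z)
        assert (out["label"] == "neither").all()


class TestBootstrapCompare:
    def _profiles(self, rng, shift, n=12):
        rows = []
        for s in range(n):
            for sec in (1, 2, 4, 5):
                rows.append({"subject_id": f"x{s}", "section": sec,
                             "sms_normalized": np.clip(0.5 + shift + rng.normal(0, 0.05), 0, 1)})
        return pd.DataFrame(rows)

    def test_sign_flip_on_swap(self, rng):
        a = self._profiles(rng, 0.2)
        b = self._profiles(rng, -0.2)
        ab = bootstrap_compare(a, b, n_boot=200, seed=1)
        ba = bootstrap_compare(b, a, n_boot=200, seed=1)
        assert np.allclose(ab["diff"], -ba["diff"])

    def test_detects_planted_difference(self, rng):
        a = self._profiles(rng, 0.2)
        b = self._profiles(rng, -0.2)
        out = bootstrap_compare(a, b, n_boot=500, seed=2)
        assert (out["diff"] > 0).all()
        assert (out["p"] < 0.05).all()

    def test_small_groups_raise(self, rng):
        a = self._profiles(rng, 0.0, n=1)
        b = self._profiles(rng, 0.0, n=5)
        with pytest.raises(ValueError):
            bootstrap_compare(a, b, n_boot=100)


def test_subject_sms_recovers_planted_direction(small_cfg, baseline_phenotypes):
    from socpd.synth import generate_imaging

    fix = generate_imaging(small_cfg, baseline_phenotypes.head(40))
    ph = baseline_phenotypes.set_index("subject_id")["true_phenotype"]
    rows = []
    for sid, conn in fix.lc_connectivity.items():
        prof = subject_sms(conn, fix.lc_voxel_z)
        prof["subject_id"] = sid
        rows.append(prof)
    sms = pd.concat(rows).reset_index(drop=True)
    sms["phenotype"] = sms["subject_id"].map(ph)
    caudal = sms[sms["region"] == "caudal"].groupby("phenotype")["sms_normalized"].mean()
    # caudal sections resemble the middle in body-first fields
    assert caudal["body_first"] > caudal["brain_first"]
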