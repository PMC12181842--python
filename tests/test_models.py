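import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from socpd.models import (
    dementia_endpoint,
    fdr_adjust,
    fit_cox,
    fit_trajectory,
    mediate,
)


def make_longitudinal(n=120, slope_diff=0.5, resid_sd=1.0, seed=0, times=(0, 1, 2, 3)):
    rng = np.random.default_rng(seed)
    half = n // 2
    group = np.array(["brain_first"] * half + ["body_first"] * (n - half))
    intercept = rng.normal(20, 2, n)
    age = rng.normal(65, 8, n)
    sex = rng.integers(0, 2, n)
    dur = rng.uniform(0, 3, n)
    rows = []
    for i in range(n):
        slope = 1.0 + (slope_diff if group[i] == "body_first" else 0.0)
        for t in times:
            rows.append({
                "subject_id": f"s{i}", "phenotype": group[i], "time_years": float(t),
                "age": age[i], "sex": sex[i], "disease_duration": dur[i],
                "y": intercept[i] + slope * t + rng.normal(0, resid_sd),
            })
    return pd.DataFrame(rows)


class TestTrajectory:
    def test_recovers_planted_slope_difference(self):
        df = make_longitudinal(n=200, slope_diff=0.5, seed=1)
        res = fit_trajectory(df, "y", comparison_level="body_first")
        beta = res.loc[res["term"] == "group:time", "beta"].iloc[0]
        assert beta == pytest.approx(0.5, abs=0.15)

    def test_comparison_level_flips_sign(self):
        df = make_longitudinal(n=120, slope_diff=0.5, seed=2)
        a = fit_trajectory(df, "y", comparison_level="body_first")
        b = fit_trajectory(df, "y", comparison_level="brain_first")
        ba = a.loc[a["term"] == "group:time", "beta"].iloc[0]
        bb = b.loc[b["term"] == "group:time", "beta"].iloc[0]
        assert ba == pytest.approx(-bb, abs=1e-6)

    def test_constant_covariate_dropped_with_warning(self):
        df = make_longitudinal(n=60, seed=3)
        df["disease_duration"] = 0.0
        with pytest.warns(UserWarning, match="constant covariate"):
            res = fit_trajectory(df, "y")
        assert "disease_duration" not in set(res["term"])

    def test_nonbinary_group_raises(self):
        df = make_longitudinal(n=60, seed=4)
        df.loc[df.index[:20], "phenotype"] = "other"
        with pytest.raises(ValueError, match="binary"):
            fit_trajectory(df, "y")

    def test_unknown_comparison_level_raises(self):
        df = make_longitudinal(n=60, seed=5)
        with pytest.raises(ValueError):
            fit_trajectory(df, "y", comparison_level="nope")

    def test_education_added_for_cognitive_outcomes(self):
        df = make_longitudinal(n=80, seed=6).rename(columns={"y": "moca"})
        df["education"] = np.random.default_rng(0).normal(15, 3, len(df))
        res = fit_trajectory(df, "moca")
        assert "education" in set(res["term"])


class TestDementiaEndpoint:
    def test_strictly_below_cutoff(self):
        v = pd.DataFrame({
            "subject_id": ["a"] * 3 + ["b"] * 3,
            "time_years": [0.0, 1.0, 2.0] * 2,
            "moca": [25, 21, 20, 25, 24, 23],
        })
        out = dementia_endpoint(v).set_index("subject_id")
        # exactly 21 never triggers; first visit below 21 does
        assert out.loc["a", "event"] == 1 and out.loc["a", "duration"] == 2.0
        assert out.loc["b", "event"] == 0 and out.loc["b", "duration"] == 2.0

    def test_censoring_at_last_observed_visit(self):
        v = pd.DataFrame({"subject_id": ["c", "c"], "time_years": [0.0, 3.0],
                          "moca": [28, 27]})
        out = dementia_endpoint(v)
        assert out.iloc[0]["duration"] == 3.0 and out.iloc[0]["event"] == 0


class TestCox:
    def _surv(self, hr=2.0, n=400, seed=0):
        rng = np.random.default_rng(seed)
        half = n // 2
        group = np.array(["brain_first"] * half + ["body_first"] * (n - half))
        rate = np.where(group == "body_first", 0.1 * hr, 0.1)
        t = rng.exponential(1 / rate)
        horizon = 8.0
        return pd.DataFrame({
            "duration": np.minimum(t, horizon),
            "event": (t <= horizon).astype(int),
            "phenotype": group,
            "age": rng.normal(65, 8, n),
            "sex": rng.integers(0, 2, n),
            "education": rng.normal(15, 3, n),
        })

    def test_recovers_hazard_ratio_direction(self):
        df = self._surv(hr=2.0, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = fit_cox(df, comparison_level="body_first")
        assert 1.4 < out["hr"] < 2.8
        assert out["group_comparison"] == "body_first"

    def test_no_events_raises(self):
        df = self._surv(seed=2)
        df["event"] = 0
        with pytest.raises(ValueError, match="no events"):
            fit_cox(df)

    def test_one_group_without_events_raises(self):
        df = self._surv(seed=3)
        df.loc[df["phenotype"] == "brain_first", "event"] = 0
        with pytest.raises(ValueError, match="per group"):
            fit_cox(df)


def bh_oracle(p, q=0.05):
    """Literal BH step-up: largest k with p_(k) <= k q / m rejected."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_max = k
    reject = np.zeros(m, bool)
    reject[order[:k_max]] = True
    return reject


class TestFDR:
    def test_matches_brute_force_on_exhaustive_small_sets(self):
        grid = [0.001, 0.01, 0.04, 0.05, 0.2, 0.8]
        for combo in itertools.product(grid, repeat=3):
            _, rej = fdr_adjust(np.array(combo))
            assert np.array_equal(rej, bh_oracle(combo))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            adj, rej = fdr_adjust(p)
            rej_sm, adj_sm, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            assert np.allclose(adj, adj_sm, atol=1e-12)
            assert np.array_equal(rej, rej_sm)

    def test_monotone_and_bounded(self, rng):
        p = rng.random(30)
        adj, _ = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0) and np.all(adj >= p - 1e-12)

    def test_empty_and_invalid(self):
        adj, rej = fdr_adjust([])
        assert adj.size == 0 and rej.size == 0
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestMediation:
    def _construct(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n).astype(float)
        m = 1.0 * x + rng.normal(0, 0.5, n)
        y = 0.85 * x + 0.15 * m + rng.normal(0, 0.1, n)
        return pd.DataFrame({"x": x, "m": m, "y": y})

    def test_recovers_paths(self):
        df = self._construct(seed=1)
        res = mediate(df, "x", "m", "y", n_boot=500, seed=0)
        assert res.a == pytest.approx(1.0, abs=0.1)
        assert res.b == pytest.approx(0.15, abs=0.05)
        assert res.proportion_mediated == pytest.approx(0.15, abs=0.05)
        assert res.ci_low < res.indirect < res.ci_high
        assert not res.opposite_signs

    def test_null_mediator_not_significant(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({
            "x": rng.integers(0, 2, 300).astype(float),
            "m": rng.normal(size=300),
        })
        df["y"] = df["x"] + rng.normal(0, 0.5, 300)
        res = mediate(df, "x", "m", "y", n_boot=500, seed=0)
        assert res.p > 0.05
        assert abs(res.indirect) < 0.1

    def test_opposite_signs_flagged_not_clamped(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 300).astype(float)
        m = 1.0 * x + rng.normal(0, 0.3, 300)
        y = 1.0 * x - 0.5 * m + rng.normal(0, 0.1, 300)
        res = mediate(pd.DataFrame({"x": x, "m": m, "y": y}), "x", "m", "y",
                      n_boot=500, seed=0)
        assert res.opposite_signs
        assert res.proportion_mediated < 0 or res.proportion_mediated > 1

    def test_few_boot_warns(self):
        df = self._construct(n=50, seed=2)
        with pytest.warns(UserWarning, match="bootstrap"):
            mediate(df, "x", "m", "y", n_boot=200, seed=0)

    def test_too_few_rows_raises(self):
        df = self._construct(n=5, seed=4)
        with pytest.raises(ValueError):
            mediate(df, "x", "m", "y", n_boot=500)
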