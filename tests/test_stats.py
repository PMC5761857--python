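import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from pcdquant import (CohortSimSpec, SchemaError, SingularDesignError,
                      compare_dependent_correlations, compare_groups,
                      generate_cohort, sector_contrasts,
                      sector_correlation_difference, univariate_fit)

GROUPS = ("control", "naion", "fellow", "poag")


def _cohort(seed=0, **kw):
    return generate_cohort(CohortSimSpec(seed=seed, **kw))


class TestCompareGroups:
    def test_study_sized_cohort_patient_groups_lower(self):
        gc = compare_groups(_cohort(seed=1), "pcd_whole_pct")
        assert gc.model == "mixed"
        t = gc.contrasts.set_index(["group_a", "group_b"])
        for pair in [("control", "naion"), ("control", "poag"),
                     ("fellow", "naion"), ("fellow", "poag")]:
            row = t.loc[pair]
            assert row["estimate"] > 0
            assert row["p_bonf"] < 0.001

    def test_bonferroni_monotone_and_bounded(self):
        gc = compare_groups(_cohort(seed=2), "pcd_annulus_pct")
        assert (gc.contrasts["p_bonf"] >= gc.contrasts["p_raw"] - 1e-15).all()
        assert (gc.contrasts["p_bonf"] <= 1.0).all()
        assert gc.bonferroni_family == 6

    def test_one_eye_per_subject_matches_ols(self):
        df = _cohort(seed=3)
        df = df[df.laterality == "OD"].copy()
        gc = compare_groups(df, "pcd_whole_pct")
        assert gc.model == "ols"
        # independent OLS fit with the same fixed effects
        enc = df.copy()
        enc["sex"] = (enc["sex"] == "F").astype(float)
        ref = sorted(enc["group"].unique())[0]
        res = smf.ols(
            f"pcd_whole_pct ~ C(group, Treatment(reference={ref!r})) + "
            "age_years + sex + axial_length_mm", data=enc).fit()
        for _, row in gc.contrasts.iterrows():
            a = 0.0 if row.group_a == ref else res.params[
                f"C(group, Treatment(reference={ref!r}))[T.{row.group_a}]"]
            b = 0.0 if row.group_b == ref else res.params[
                f"C(group, Treatment(reference={ref!r}))[T.{row.group_b}]"]
            assert row.estimate == pytest.approx(a - b, abs=1e-6)

    def test_null_pvalues_roughly_uniform(self):
        # two identically-drawn groups: raw pairwise p should be null-distributed
        from scipy import stats as sps
        pvals, ests = [], []
        for seed in range(40):
            df = _cohort(seed=100 + seed,
                         n_subjects={"control": 100, "naion": 2, "fellow": 2, "poag": 2})
            sub = df[df.group == "control"].copy()
            subjects = sub["subject_id"].unique()
            relabel = {s: ("a" if i < 50 else "b") for i, s in enumerate(subjects)}
            sub["group"] = sub["subject_id"].map(relabel)
            gc = compare_groups(sub, "pcd_whole_pct")
            pvals.append(float(gc.contrasts["p_raw"].iloc[0]))
            ests.append(float(gc.contrasts["estimate"].iloc[0]))
        assert sps.kstest(pvals, "uniform").pvalue > 0.01
        # no systematic group difference: mean estimate within 3.5 SE of zero
        sem = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests)) < 3.5 * sem

    def test_injected_difference_ci_coverage(self):
        # delta = 10 on SD 2 with 50 eyes per group: the 95% CI should cover
        # the true difference in >= 93% of seeded replicates
        rng = np.random.default_rng(7)
        covered = 0
        n_rep = 200
        for _ in range(n_rep):
            rows = []
            for g, mu in (("a", 30.0), ("b", 40.0)):
                for s in range(25):
                    u = rng.normal()
                    for lat in ("OD", "OS"):
                        e = rng.normal()
                        rows.append({
                            "subject_id": f"{g}{s}", "group": g,
                            "pcd_whole_pct": mu + 2.0 * (np.sqrt(.4) * u + np.sqrt(.6) * e),
                            "age_years": rng.normal(60, 8), "sex": rng.choice(["F", "M"]),
                            "axial_length_mm": rng.normal(23, 1.3),
                        })
            gc = compare_groups(pd.DataFrame(rows), "pcd_whole_pct")
            row = gc.contrasts.iloc[0]
            lo, hi = sorted((row.ci_low, row.ci_high))
            if lo <= -10.0 <= hi or lo <= 10.0 <= hi:
                covered += 1
        assert covered / n_rep >= 0.93

    def test_constant_covariate_rejected(self):
        df = _cohort(seed=4)
        df["axial_length_mm"] = 23.0
        with pytest.raises(SingularDesignError, match="axial_length_mm"):
            compare_groups(df, "pcd_whole_pct")

    def test_missing_columns_rejected(self):
        with pytest.raises(SchemaError):
            compare_groups(pd.DataFrame({"pcd_whole_pct": [1, 2]}), "pcd_whole_pct")

    def test_single_group_rejected(self):
        df = _cohort(seed=5)
        with pytest.raises(SingularDesignError):
            compare_groups(df[df.group == "poag"], "pcd_whole_pct")


class TestSectorContrasts:
    SECTOR_COLS = ["pcd_sup_pct", "pcd_nas_pct", "pcd_inf_pct", "pcd_temp_pct"]

    def test_identical_sectors_give_zero_and_p1(self):
        df = _cohort(seed=6)
        for col in self.SECTOR_COLS:
            df[col] = df["pcd_annulus_pct"]
        out = sector_contrasts(df, "control")
        assert (out["estimate"] == 0).all()
        assert (out["p_bonf"] == 1.0).all()

    def test_estimates_equal_mean_within_eye_differences(self):
        df = _cohort(seed=7)
        out = sector_contrasts(df, "poag").set_index(["sector_a", "sector_b"])
        sub = df[df.group == "poag"]
        expected = (sub["pcd_sup_pct"] - sub["pcd_nas_pct"]).mean()
        assert out.loc[("superior", "nasal"), "estimate"] == pytest.approx(expected)

    def test_shifted_superior_detected(self):
        df = _cohort(seed=8, n_subjects={"control": 50, "naion": 2, "fellow": 2, "poag": 2})
        df.loc[df.group == "control", "pcd_sup_pct"] -= 5.0
        out = sector_contrasts(df, "control").set_index(["sector_a", "sector_b"])
        for other in ("nasal", "inferior", "temporal"):
            assert out.loc[("superior", other), "p_bonf"] < 0.05

    def test_missing_rows_dropped_with_warning(self):
        df = _cohort(seed=9)
        df.loc[df[df.group == "control"].index[:4], "pcd_sup_pct"] = np.nan
        with pytest.warns(UserWarning, match="dropped 4 rows"):
            sector_contrasts(df, "control")


class TestUnivariateFit:
    def test_perfect_collinearity(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": 2.0 * np.arange(10.0)})
        fit = univariate_fit(df, "y", "x")
        assert fit.r == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_r_is_signed_sqrt_r2(self, rng):
        x = rng.normal(size=400)
        y = -0.5 * x + rng.normal(size=400)
        fit = univariate_fit(pd.DataFrame({"x": x, "y": y}), "y", "x")
        assert fit.r == pytest.approx(-np.sqrt(fit.r2))
        assert fit.r < 0

    def test_bivariate_normal_rho_half(self, rng):
        n = 5000
        x = rng.normal(size=n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=n)
        fit = univariate_fit(pd.DataFrame({"x": x, "y": y}), "y", "x")
        assert 0.47 <= fit.r <= 0.53

    def test_slope_ci_contains_truth(self, rng):
        x = rng.normal(size=500)
        y = 3.0 + 1.5 * x + rng.normal(size=500)
        fit = univariate_fit(pd.DataFrame({"x": x, "y": y}), "y", "x")
        assert fit.ci_low <= 1.5 <= fit.ci_high

    def test_zero_variance_predictor_rejected(self):
        df = pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)})
        with pytest.raises(SingularDesignError):
            univariate_fit(df, "y", "x")

    def test_too_few_pairs_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(SingularDesignError):
            univariate_fit(df, "y", "x")


def _perm_p(Z, n_perm, rng):
    """Within-eye permutation oracle: swap the two (PCD, RNFL) sector pairs
    eye-by-eye and recompute the correlation difference."""
    x1, y1, x2, y2 = Z.T
    obs = abs(np.corrcoef(x1, y1)[0, 1] - np.corrcoef(x2, y2)[0, 1])
    sw = rng.random((n_perm, len(x1))) < 0.5

    def corr(a, b):
        a = a - a.mean(1, keepdims=True)
        b = b - b.mean(1, keepdims=True)
        return (a * b).sum(1) / np.sqrt((a * a).sum(1) * (b * b).sum(1))

    stat = np.abs(corr(np.where(sw, x2, x1), np.where(sw, y2, y1))
                  - corr(np.where(sw, x1, x2), np.where(sw, y1, y2)))
    return (1 + (stat >= obs - 1e-12).sum()) / (n_perm + 1)


class TestDependentCorrelations:
    INTER = {"r_jh": 0.4, "r_jm": 0.2, "r_kh": 0.2, "r_km": 0.4}

    def test_equal_correlations_give_p1(self):
        cc = compare_dependent_correlations(0.5, 0.5, 100, self.INTER)
        assert cc.difference == 0.0
        assert cc.z == 0.0
        assert cc.p == 1.0

    def test_published_worked_example(self):
        # superior vs nasal sector correlations implied by the published R^2
        cc = compare_dependent_correlations(np.sqrt(0.57), np.sqrt(0.18), 119)
        assert round(cc.difference, 2) == 0.33

    def test_antisymmetry(self):
        a = compare_dependent_correlations(0.7, 0.4, 200, self.INTER)
        swapped = {"r_jh": 0.4, "r_jm": 0.2, "r_kh": 0.2, "r_km": 0.4}
        b = compare_dependent_correlations(0.4, 0.7, 200, swapped)
        assert b.difference == pytest.approx(-a.difference)
        assert b.p == pytest.approx(a.p)
        assert b.z == pytest.approx(-a.z)

    def test_conservative_default_flagged(self):
        with_c = compare_dependent_correlations(0.6, 0.3, 150, self.INTER)
        without = compare_dependent_correlations(0.6, 0.3, 150)
        assert without.assumed_independent
        assert not with_c.assumed_independent
        assert without.p > with_c.p  # positive dependence sharpens the test

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            compare_dependent_correlations(0.5, 0.3, 3)

    def test_non_psd_matrix_rejected(self):
        bad = {"r_jh": 0.95, "r_jm": -0.95, "r_kh": 0.95, "r_km": 0.95}
        with pytest.raises(ValueError, match="semidefinite"):
            compare_dependent_correlations(0.9, -0.9, 100, bad)

    def test_agrees_with_permutation_oracle(self):
        R = np.array([[1, .5, .4, .2], [.5, 1, .2, .4],
                      [.4, .2, 1, .5], [.2, .4, .5, 1]])
        L = np.linalg.cholesky(R)
        for seed in (0, 3):
            rng = np.random.default_rng(seed)
            Z = rng.standard_normal((1000, 4)) @ L.T
            C = np.corrcoef(Z, rowvar=False)
            cc = compare_dependent_correlations(
                C[0, 1], C[2, 3], 1000,
                {"r_jh": C[0, 2], "r_jm": C[0, 3], "r_kh": C[1, 2], "r_km": C[1, 3]})
            assert abs(cc.p - _perm_p(Z, 5000, rng)) <= 0.02

    def test_sector_difference_from_cohort_table(self):
        # within one group, where the generating correlations apply directly
        df = _cohort(seed=10, n_subjects={"control": 1000, "naion": 2,
                                          "fellow": 2, "poag": 2})
        cc = sector_correlation_difference(df[df.group == "control"],
                                           "superior", "nasal")
        # generating correlations sqrt(.57) vs sqrt(.18): difference ~ 0.33
        assert cc.difference == pytest.approx(np.sqrt(0.57) - np.sqrt(0.18), abs=0.05)
        assert cc.p < 0.001
        assert not cc.assumed_independent
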