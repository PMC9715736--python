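"""Statistics layer against independent hand-coded oracles (and pingouin as
an external cross-check for the partial correlation)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from eegmicrostates import (
    linear_fit,
    partial_corr,
    pearson_corr,
    two_factor_anova,
    welch_ttest,
    welch_ttest_per_feature,
)
from eegmicrostates.stats import ancova_group_effect, scale_correlation_table


def welch_oracle(a, b):
    """Textbook Welch t, Welch-Satterthwaite df, two-tailed p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


def patients_frame(x, y, age=None):
    n = len(x)
    return pd.DataFrame({
        "group": ["patient"] * n, "f": x, "s": y,
        "age": age if age is not None else np.zeros(n),
    })


class TestWelch:
    def test_matches_hand_oracle(self):
        a, b = [1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        t, df, p = welch_oracle(a, b)
        res = welch_ttest(a, b)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_identical_groups(self):
        res = welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_equals_student_under_equal_variance_and_n(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=12), rng.normal(size=12)
        student = sps.ttest_ind(a, b, equal_var=True)
        res = welch_ttest(a, b)
        # equal n: t statistics agree exactly; df and p only if variances match
        assert res.statistic == pytest.approx(student.statistic, abs=1e-10)
        b_matched = (b - b.mean()) / b.std(ddof=1) * a.std(ddof=1) + b.mean()
        res2 = welch_ttest(a, b_matched)
        student2 = sps.ttest_ind(a, b_matched, equal_var=True)
        assert res2.df == pytest.approx(2 * len(a) - 2, abs=1e-10)
        assert res2.p == pytest.approx(student2.pvalue, abs=1e-10)

    def test_welch_df_never_exceeds_pooled_df(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(0, rng.uniform(0.5, 3), rng.integers(3, 15))
            b = rng.normal(0, rng.uniform(0.5, 3), rng.integers(3, 15))
            res = welch_ttest(a, b)
            assert res.df <= len(a) + len(b) - 2 + 1e-12

    def test_zero_variance_flagged(self):
        res = welch_ttest([1.0, 1.0], [1.0, 1.0])
        assert "zero variance" in res.note and res.p == 1.0

    def test_per_feature_and_fdr_monotone(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "group": ["patient"] * 10 + ["healthy"] * 10,
            "f1": rng.normal(size=20), "f2": np.r_[rng.normal(2, 1, 10), rng.normal(0, 1, 10)],
        })
        raw = welch_ttest_per_feature(df, ["f1", "f2"])
        adj = welch_ttest_per_feature(df, ["f1", "f2"], fdr=True)
        for r, q in zip(raw, adj):
            assert q.p >= r.p - 1e-15


class TestPearson:
    def test_hand_computed_example(self):
        df = patients_frame([1, 2, 3, 4], [2, 1, 4, 3])
        res = pearson_corr(df, "f", "s")
        assert res.statistic == pytest.approx(0.6, abs=1e-12)

    def test_perfect_line(self):
        df = patients_frame([1, 2, 3, 4], [3, 5, 7, 9])
        assert pearson_corr(df, "f", "s").statistic == pytest.approx(1.0)

    def test_p_value_matches_t_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=15)
        y = x + rng.normal(size=15)
        res = pearson_corr(patients_frame(x, y), "f", "s")
        r, n = res.statistic, 15
        t = r * np.sqrt((n - 2) / (1 - r**2))
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), n - 2), abs=1e-10)

    def test_zero_variance_flagged(self):
        res = pearson_corr(patients_frame([1, 1, 1], [1, 2, 3]), "f", "s")
        assert np.isnan(res.statistic) and "zero variance" in res.note


class TestPartialCorr:
    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(4)
        n = 20
        z = rng.normal(size=n)
        x = 0.5 * z + rng.normal(size=n)
        y = -0.3 * z + rng.normal(size=n)
        res = partial_corr(patients_frame(x, y, age=z), "f", "s", control="age")
        rx = x - np.polyval(np.polyfit(z, x, 1), z)
        ry = y - np.polyval(np.polyfit(z, y, 1), z)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.statistic == pytest.approx(oracle, abs=1e-10)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        n = 25
        z = rng.normal(size=n)
        x = z + rng.normal(size=n)
        y = z + rng.normal(size=n)
        res = partial_corr(patients_frame(x, y, age=z), "f", "s", control="age")
        ref = pingouin.partial_corr(pd.DataFrame({"x": x, "y": y, "z": z}),
                                    x="x", y="y", covar="z")
        assert res.statistic == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert res.p == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-8)

    def test_uncorrelated_control_close_to_simple_r(self):
        rng = np.random.default_rng(6)
        n = 2000
        z = rng.normal(size=n)
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)
        simple = pearson_corr(patients_frame(x, y), "f", "s").statistic
        partial = partial_corr(patients_frame(x, y, age=z), "f", "s").statistic
        assert partial == pytest.approx(simple, abs=0.01)

    def test_constant_control_equals_simple_correlation(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=10)
        y = x + rng.normal(size=10)
        df = patients_frame(x, y, age=np.full(10, 60.0))
        res = partial_corr(df, "f", "s", control="age")
        assert res.statistic == pytest.approx(
            pearson_corr(df, "f", "s").statistic, abs=1e-12)

    def test_control_equal_to_variable_rejected(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=10)
        df = patients_frame(rng.normal(size=10), y, age=y)
        with pytest.raises(ValueError):
            partial_corr(df, "f", "s", control="age")


class TestAnova:
    @staticmethod
    def balanced_frame():
        # balanced 2x2 with known cell means and fixed residuals
        resid = np.tile([0.5, -0.5], 8)
        cells = []
        for g, gv in (("patient", 2.0), ("healthy", 0.0)):
            for a, av in (("younger", 1.0), ("older", 0.0)):
                cells += [{"group": g, "age_bin": a, "y": gv + av} for _ in range(4)]
        df = pd.DataFrame(cells)
        df["y"] += resid
        return df

    def test_balanced_design_matches_hand_sums_of_squares(self):
        df = self.balanced_frame()
        res = {r.feature.split(":")[1]: r for r in two_factor_anova(df, "y")}
        n = len(df)
        grand = df["y"].mean()
        ss_a = sum(len(g) * (g["y"].mean() - grand) ** 2
                   for _, g in df.groupby("group"))
        ss_b = sum(len(g) * (g["y"].mean() - grand) ** 2
                   for _, g in df.groupby("age_bin"))
        ss_resid = sum(
            ((g["y"] - g["y"].mean()) ** 2).sum()
            for _, g in df.groupby(["group", "age_bin"]))
        # additive model residual = cell residual + interaction SS (balanced)
        ss_tot = ((df["y"] - grand) ** 2).sum()
        ss_err = ss_tot - ss_a - ss_b
        ms_err = ss_err / (n - 3)
        assert res["group"].statistic == pytest.approx((ss_a / 1) / ms_err, abs=1e-10)
        assert res["age_bin"].statistic == pytest.approx((ss_b / 1) / ms_err, abs=1e-10)

    def test_planted_group_effect_detected_age_not(self):
        rng = np.random.default_rng(9)
        n = 40
        df = pd.DataFrame({
            "group": ["patient"] * (n // 2) + ["healthy"] * (n // 2),
            "age": rng.uniform(20, 80, n),
        })
        df["y"] = np.where(df.group == "patient", 2.0, 0.0) + rng.normal(size=n)
        res = {r.feature.split(":")[1]: r for r in two_factor_anova(df, "y")}
        assert res["group"].p < 0.05
        assert res["age_bin"].p > 0.05

    def test_constant_response_flagged(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame({"group": ["patient"] * 8 + ["healthy"] * 8,
                           "age": rng.uniform(20, 80, 16), "y": 5.0})
        for r in two_factor_anova(df, "y"):
            assert r.statistic == 0.0 and r.p == 1.0
            assert "constant response" in r.note

    def test_aliased_factors_rejected(self):
        df = pd.DataFrame({
            "group": ["patient"] * 6 + ["healthy"] * 6,
            "age_bin": ["older"] * 6 + ["younger"] * 6,
            "y": np.arange(12.0),
        })
        with pytest.raises(ValueError, match="aliased"):
            two_factor_anova(df, "y")

    def test_ancova_group_effect_runs(self):
        df = self.balanced_frame()
        df["age"] = np.where(df["age_bin"] == "older", 70.0, 30.0) + np.arange(len(df))
        res = ancova_group_effect(df, "y")
        assert res.p < 0.05 and res.kind == "ancova_F"


class TestLinearFit:
    def test_exact_line(self):
        df = patients_frame([0, 1, 2, 3], [1, 3, 5, 7])
        slope, intercept, r2 = linear_fit(df, "f", "s")
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0), abs=1e-12)

    def test_r_squared_equals_squared_pearson(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        df = patients_frame(x, y)
        _, _, r2 = linear_fit(df, "f", "s")
        r = pearson_corr(df, "f", "s").statistic
        assert r2 == pytest.approx(r**2, abs=1e-12)

    def test_four_point_example(self):
        df = patients_frame([1, 2, 3, 4], [2, 1, 4, 3])
        assert linear_fit(df, "f", "s")[2] == pytest.approx(0.36, abs=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_fit(patients_frame([1, 1, 1], [1, 2, 3]), "f", "s")


def test_scale_correlation_table_shape():
    rng = np.random.default_rng(11)
    n = 12
    df = pd.DataFrame({
        "group": ["patient"] * n, "age": rng.uniform(40, 80, n),
        "Dur_A": rng.normal(80, 10, n), "C-D": rng.uniform(0.1, 0.4, n),
        "fma_total": rng.uniform(30, 90, n), "fma_lower": rng.uniform(5, 34, n),
    })
    table = scale_correlation_table(df, ["Dur_A", "C-D"],
                                    scales=["fma_total", "fma_lower"])
    assert len(table) == 4
    assert set(table.columns) >= {"r", "p", "partial_r", "partial_p"}
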