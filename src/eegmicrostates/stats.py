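"""Group-difference and clinical-scale statistics on a cohort table.

The cohort table has one row per subject: the 28 microstate feature
columns (16 per-class features + 12 transition probabilities) plus
metadata (``group``, ``age``, ``sex``) and clinical scales (FMA total /
upper / lower, IADL; present for patients only).

Conventions, fixed package-wide: all tests are two-tailed at alpha = 0.05;
group comparisons use Welch's unequal-variance t-test (microstate features
routinely violate homogeneity of variance across clinical groups); scale
correlations are computed within the patient group only, optionally as
first-order partial correlations controlling for age.  No multiplicity
correction is applied by default (each of the 28 tests is reported as-is);
Benjamini-Hochberg adjusted p-values are available behind a flag, with the
caveat that they change the decision rule, not the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05

SCALE_COLUMNS = ["fma_total", "fma_upper", "fma_lower", "iadl"]


@dataclass
class TestResult:
    """One statistical test: statistic, two-tailed p, degrees of freedom."""

    feature: str
    kind: str                      # "welch_t" | "pearson_r" | "partial_r" | "anova_F" | ...
    statistic: float
    p: float
    df: float
    n: int
    ci: tuple[float, float] | None = None
    note: str = ""

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p) and self.p < ALPHA)

    def as_dict(self) -> dict:
        return {
            "feature": self.feature, "kind": self.kind,
            "statistic": self.statistic, "df": self.df, "p": self.p,
            "n": self.n,
            "ci_low": None if self.ci is None else self.ci[0],
            "ci_high": None if self.ci is None else self.ci[1],
            "note": self.note,
        }


def results_table(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


def welch_ttest(a: np.ndarray, b: np.ndarray, feature: str = "") -> TestResult:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df.

    Convention: statistic = mean(a) - mean(b) scaled by the unpooled
    standard error (``a`` = patient group first in cohort use).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        equal = a.mean() == b.mean()
        return TestResult(feature, "welch_t", 0.0 if equal else np.inf,
                          1.0 if equal else 0.0, np.nan, len(a) + len(b),
                          note="zero variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(1 - ALPHA)
    return TestResult(feature, "welch_t", float(res.statistic), float(res.pvalue),
                      float(res.df), len(a) + len(b),
                      ci=(float(ci.low), float(ci.high)))


def welch_ttest_per_feature(
    cohort: pd.DataFrame,
    feature_names: list[str],
    group_col: str = "group",
    groups: tuple[str, str] = ("patient", "healthy"),
    fdr: bool = False,
) -> list[TestResult]:
    """Welch's t-test for each feature column, patient minus healthy.

    With ``fdr=True`` the reported p-values are Benjamini-Hochberg adjusted
    across the supplied features.
    """
    a_rows = cohort[cohort[group_col] == groups[0]]
    b_rows = cohort[cohort[group_col] == groups[1]]
    out = [
        welch_ttest(a_rows[f].to_numpy(float), b_rows[f].to_numpy(float), feature=f)
        for f in feature_names
    ]
    if fdr:
        finite = [r for r in out if np.isfinite(r.p)]
        adj = multipletests([r.p for r in finite], method="fdr_bh")[1]
        for r, p in zip(finite, adj):
            r.p = float(p)
            r.note = (r.note + " BH-adjusted").strip()
    return out


def pearson_corr(cohort: pd.DataFrame, feature: str, scale: str,
                 group: str | None = "patient") -> TestResult:
    """Sample Pearson r with two-tailed p (t transform) and Fisher-z CI."""
    df = cohort if group is None else cohort[cohort["group"] == group]
    pair = df[[feature, scale]].dropna()
    x = pair[feature].to_numpy(float)
    y = pair[scale].to_numpy(float)
    n = len(x)
    if n < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        return TestResult(f"{feature}~{scale}", "pearson_r", np.nan, np.nan,
                          n - 2, n, note="zero variance")
    res = sps.pearsonr(x, y)
    ci = res.confidence_interval(1 - ALPHA)
    return TestResult(f"{feature}~{scale}", "pearson_r", float(res.statistic),
                      float(res.pvalue), n - 2, n,
                      ci=(float(ci.low), float(ci.high)))


def partial_corr(cohort: pd.DataFrame, feature: str, scale: str,
                 control: str = "age", group: str | None = "patient") -> TestResult:
    """First-order partial correlation controlling for one variable.

    ``r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))`` with a
    two-tailed p on ``df = n - 3``.  A zero-variance control reduces to the
    simple correlation (nothing to remove); a control perfectly collinear
    with either variable leaves the partial correlation undefined.
    """
    df = cohort if group is None else cohort[cohort["group"] == group]
    trio = df[[feature, scale, control]].dropna()
    x = trio[feature].to_numpy(float)
    y = trio[scale].to_numpy(float)
    z = trio[control].to_numpy(float)
    n = len(x)
    if n < 4:
        raise ValueError("partial correlation needs n >= 4")
    if z.std() == 0:
        base = pearson_corr(trio.assign(group="patient"), feature, scale, group=None)
        base.kind = "partial_r"
        base.note = "constant control; equals simple correlation"
        return base
    r_xy = float(np.corrcoef(x, y)[0, 1])
    r_xz = float(np.corrcoef(x, z)[0, 1])
    r_yz = float(np.corrcoef(y, z)[0, 1])
    denom = (1 - r_xz**2) * (1 - r_yz**2)
    if denom <= 0:
        raise ValueError("control variable is perfectly collinear with x or y")
    r = (r_xy - r_xz * r_yz) / np.sqrt(denom)
    dof = n - 3
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1 - r**2))
        p = float(2 * sps.t.sf(abs(t), dof))
    return TestResult(f"{feature}~{scale}|{control}", "partial_r", r, p, dof, n)


def two_factor_anova(
    cohort: pd.DataFrame,
    response: str,
    factors: tuple[str, str] = ("group", "age_bin"),
    interaction: bool = False,
) -> list[TestResult]:
    """Two-factor ANOVA with type-II sums of squares.

    If the second factor is ``age_bin`` and the column is absent, age is
    binned at the cohort median.  Returns one result per factor (plus the
    interaction when requested).  Aliased (confounded) factors raise.
    """
    df = cohort.copy()
    f1, f2 = factors
    if f2 == "age_bin" and "age_bin" not in df.columns:
        med = df["age"].median()
        df["age_bin"] = np.where(df["age"] <= med, "younger", "older")
    if df[response].nunique() <= 1:
        return [
            TestResult(f"{response}:{f}", "anova_F", 0.0, 1.0, np.nan, len(df),
                       note="constant response")
            for f in (f1, f2)
        ]
    cross = pd.crosstab(df[f1], df[f2])
    if (cross.to_numpy() > 0).sum() <= max(cross.shape):
        raise ValueError(f"factors {f1} and {f2} are aliased (confounded design)")
    op = "*" if interaction else "+"
    model = smf.ols(f"Q('{response}') ~ C(Q('{f1}')) {op} C(Q('{f2}'))", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = []
    for term, row in table.iterrows():
        if term == "Residual":
            continue
        name = term
        for f in (f1, f2):
            name = name.replace(f"C(Q('{f}'))", f)
        out.append(TestResult(
            feature=f"{response}:{name}", kind="anova_F",
            statistic=float(row["F"]), p=float(row["PR(>F)"]),
            df=float(row["df"]), n=len(df),
        ))
    return out


def ancova_group_effect(cohort: pd.DataFrame, response: str,
                        covariate: str = "age") -> TestResult:
    """Group effect on ``response`` adjusting for a continuous covariate."""
    df = cohort[[response, covariate, "group"]].dropna()
    model = smf.ols(f"Q('{response}') ~ C(group) + Q('{covariate}')", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc[[t for t in table.index if "group" in t][0]]
    return TestResult(
        feature=f"{response}:group|{covariate}", kind="ancova_F",
        statistic=float(row["F"]), p=float(row["PR(>F)"]),
        df=float(row["df"]), n=len(df),
    )


def linear_fit(cohort: pd.DataFrame, x: str, y: str,
               group: str | None = "patient") -> tuple[float, float, float]:
    """Ordinary least squares of ``y`` on ``x``: (slope, intercept, R^2).

    For simple regression R^2 equals the squared Pearson correlation.
    """
    df = cohort if group is None else cohort[cohort["group"] == group]
    pair = df[[x, y]].dropna()
    if len(pair) < 3:
        raise ValueError("linear fit needs n >= 3")
    xv = pair[x].to_numpy(float)
    yv = pair[y].to_numpy(float)
    if xv.std() == 0:
        raise ValueError("zero variance in x")
    res = sps.linregress(xv, yv)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def scale_correlation_table(
    cohort: pd.DataFrame,
    feature_names: list[str],
    scales: list[str] | None = None,
    control: str = "age",
) -> pd.DataFrame:
    """Pearson and age-controlled partial correlations, patients only.

    One row per (feature, scale) pair; columns ``r``, ``p``, ``partial_r``,
    ``partial_p``, ``n``.
    """
    scales = scales or SCALE_COLUMNS
    rows = []
    for f in feature_names:
        for s in scales:
            simple = pearson_corr(cohort, f, s)
            partial = partial_corr(cohort, f, s, control=control)
            rows.append({
                "feature": f, "scale": s, "n": simple.n,
                "r": simple.statistic, "p": simple.p,
                "partial_r": partial.statistic, "partial_p": partial.p,
            })
    return pd.DataFrame(rows)
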