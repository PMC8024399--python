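"""Statistical validation of composite biomarkers.

* :func:`two_way_anova` — group × surgery ANOVA (Type II sums of squares
  for the unbalanced post-dropout design) on a composite score, with the
  four Bonferroni post hoc contrasts of interest: MDD vs non-MDD within
  each timepoint and pre vs post within each group.
* :func:`regress_madrs` — OLS of MADRS on a composite score (plus
  optional covariates), reporting the standardized coefficient and the
  partial F of the score.
* :func:`delta_regression` — over complete pre/post pairs, OLS of the
  MADRS decrease (pre − post, positive = improvement) on the biomarker
  decrease.
* :func:`cohort_tests` — the group-comparison table: Welch t-tests on
  continuous characteristics, Fisher exact tests on 2×2 counts, paired t
  on pre/post BMI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .io import CohortDesign

__all__ = [
    "AnovaResult",
    "RegressionResult",
    "two_way_anova",
    "regress_madrs",
    "delta_regression",
    "cohort_tests",
    "fisher_2x2",
    "prevalence_pct",
]


@dataclass
class RegressionResult:
    predictor: str
    beta_std: float
    F: float
    df: tuple[float, float]
    p: float
    covariates: list[str] = field(default_factory=list)
    n: int = 0

    def summary(self) -> str:
        cov = f" + {' + '.join(self.covariates)}" if self.covariates else ""
        return (
            f"MADRS ~ {self.predictor}{cov}: beta_std = {self.beta_std:.3f}, "
            f"F({self.df[0]:g},{self.df[1]:g}) = {self.F:.2f}, p = {self.p:.3g}, n = {self.n}"
        )


@dataclass
class AnovaResult:
    effects: pd.DataFrame  # index: group, timepoint, interaction; cols F, df1, df2, p
    posthoc: pd.DataFrame  # comparison, t, p_raw, p_bonferroni
    cell_means: pd.DataFrame

    @property
    def interaction_p(self) -> float:
        return float(self.effects.loc["interaction", "p"])

    def summary(self) -> str:
        lines = ["Two-way ANOVA (Type II SS), score ~ group * timepoint"]
        lines.append(self.effects.to_string(float_format=lambda v: f"{v:.4g}"))
        lines.append("Bonferroni post hoc contrasts:")
        lines.append(self.posthoc.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def _aligned(score: pd.Series, design: CohortDesign) -> pd.DataFrame:
    d = design.table.loc[score.index].copy()
    d["score"] = score.astype(float)
    return d


def two_way_anova(score: pd.Series, design: CohortDesign, typ: int = 2) -> AnovaResult:
    """Group × timepoint ANOVA with interaction on one composite score.

    ``score`` is indexed by sample id.  Timepoint is treated as a
    between-cell factor (ordinary two-way ANOVA).  Post hoc: the four
    pairwise contrasts of interest, t-tested against the model's
    residual mean square with Bonferroni correction (×4).
    """
    d = _aligned(score, design)
    counts = d.groupby(["group", "timepoint"], observed=True)["score"].count()
    if len(counts) < 4 or (counts < 2).any():
        raise ValueError(f"need >=2 observations in each group × timepoint cell:\n{counts}")
    model = smf.ols("score ~ C(group) * C(timepoint)", data=d).fit()
    table = sm.stats.anova_lm(model, typ=typ)
    rename = {
        "C(group)": "group",
        "C(timepoint)": "timepoint",
        "C(group):C(timepoint)": "interaction",
    }
    df_resid = float(model.df_resid)
    mse = float(model.mse_resid)
    effects = pd.DataFrame(
        {
            "F": [table.loc[k, "F"] for k in rename],
            "df1": [table.loc[k, "df"] for k in rename],
            "df2": df_resid,
            "p": [table.loc[k, "PR(>F)"] for k in rename],
        },
        index=list(rename.values()),
    )

    means = d.groupby(["group", "timepoint"], observed=True)["score"].agg(["mean", "count"])
    contrasts = [
        ("MDD vs nonMDD @ baseline", ("MDD", "baseline"), ("nonMDD", "baseline")),
        ("MDD vs nonMDD @ post", ("MDD", "post"), ("nonMDD", "post")),
        ("baseline vs post @ MDD", ("MDD", "baseline"), ("MDD", "post")),
        ("baseline vs post @ nonMDD", ("nonMDD", "baseline"), ("nonMDD", "post")),
    ]
    rows = []
    for label, a, b in contrasts:
        diff = means.loc[a, "mean"] - means.loc[b, "mean"]
        se = np.sqrt(mse * (1 / means.loc[a, "count"] + 1 / means.loc[b, "count"]))
        t = diff / se
        p_raw = 2 * stats.t.sf(abs(t), df_resid)
        rows.append((label, t, p_raw, min(1.0, p_raw * len(contrasts))))
    posthoc = pd.DataFrame(rows, columns=["comparison", "t", "p_raw", "p_bonferroni"])
    return AnovaResult(effects, posthoc, means)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance variable in regression")
    return (v - v.mean()) / sd


def regress_madrs(
    score: pd.Series,
    design: CohortDesign,
    covariates: list[str] | None = None,
    timepoint: str | None = "baseline",
) -> RegressionResult:
    """OLS of MADRS on the composite score, optionally adjusted.

    All variables are standardized, so the score's coefficient is the
    standardized β (the Pearson correlation in the crude model); F and p
    are the partial F-test of the score's contribution.  Restricted to
    baseline samples by default.
    """
    covariates = list(covariates or [])
    d = _aligned(score, design)
    if timepoint is not None:
        d = d[d["timepoint"] == timepoint]
    for c in covariates:
        if c not in d.columns:
            raise ValueError(f"covariate {c!r} not in design")
        if d[c].isna().any():
            raise ValueError(f"covariate {c!r} has missing values")
    y = _standardize(d["madrs"].to_numpy(dtype=float))
    xs = [_standardize(d["score"].to_numpy(dtype=float))]
    names = ["score"]
    for c in covariates:
        v = d[c]
        if v.dtype == object or str(v.dtype) == "category":
            v = pd.get_dummies(v, drop_first=True).iloc[:, 0].astype(float).to_numpy()
            if v.std(ddof=1) == 0:
                continue  # constant covariate carries no information
            xs.append(_standardize(v))
        else:
            xs.append(_standardize(v.to_numpy(dtype=float)))
        names.append(c)
    X = sm.add_constant(np.column_stack(xs))
    fit = sm.OLS(y, X).fit()
    beta = float(fit.params[1])
    t = float(fit.tvalues[1])
    F = t**2
    p = float(fit.pvalues[1])
    return RegressionResult(
        predictor=str(score.name or "score"),
        beta_std=beta,
        F=F,
        df=(1.0, float(fit.df_resid)),
        p=p,
        covariates=names[1:],
        n=len(y),
    )


def delta_regression(score: pd.Series, design: CohortDesign) -> RegressionResult:
    """Does the biomarker decrease track the MADRS decrease after surgery?

    Over complete pairs, OLS of (MADRS_pre − MADRS_post) on
    (score_pre − score_post), both standardized.
    """
    patients = design.paired_patients()
    if len(patients) < 3:
        raise ValueError(f"need >=3 complete pairs (got {len(patients)})")
    pre_ids = [design.sample_of(p, "baseline") for p in patients]
    post_ids = [design.sample_of(p, "post") for p in patients]
    missing = [s for s in pre_ids + post_ids if s not in score.index]
    if missing:
        raise ValueError(f"score missing for sample(s): {missing[:5]}")
    t = design.table
    d_madrs = t.loc[pre_ids, "madrs"].to_numpy() - t.loc[post_ids, "madrs"].to_numpy()
    d_score = score.loc[pre_ids].to_numpy() - score.loc[post_ids].to_numpy()
    y = _standardize(d_madrs.astype(float))
    if np.allclose(d_score.std(ddof=1), 0):
        raise ValueError("zero-variance score delta")
    X = sm.add_constant(_standardize(d_score.astype(float)))
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        predictor=f"delta {score.name or 'score'}",
        beta_std=float(fit.params[1]),
        F=float(fit.tvalues[1] ** 2),
        df=(1.0, float(fit.df_resid)),
        p=float(fit.pvalues[1]),
        n=len(patients),
    )


def prevalence_pct(n_cases: int, n_total: int) -> float:
    """Diagnosed prevalence as a percentage."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_cases / n_total


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p on a 2×2 count table."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def cohort_tests(design: CohortDesign, post_mdd_count: int | None = None) -> pd.DataFrame:
    """Group-comparison table mirroring a cohort characteristics table.

    Welch t-tests compare MDD vs non-MDD on continuous fields (age, BMI,
    MADRS, per timepoint where applicable); Fisher exact tests cover sex
    by group and MDD prevalence baseline vs post-surgery; a paired t
    tests the pre/post BMI drop.  ``post_mdd_count`` is the number of
    patients still meeting MDD criteria after surgery (default 0: the
    remission model the simulator implements).  Fields absent from the
    design are skipped with a note row.
    """
    t = design.table
    rows: list[dict] = []

    def welch_row(label, field, timepoint):
        sub = t[t["timepoint"] == timepoint]
        a = sub.loc[sub["group"] == "MDD", field].dropna().to_numpy(dtype=float)
        b = sub.loc[sub["group"] == "nonMDD", field].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            rows.append({"test": label, "statistic": np.nan, "p": np.nan, "note": "insufficient data"})
            return
        if np.allclose(a, a.mean()) and np.allclose(b, b.mean()) and np.isclose(a.mean(), b.mean()):
            rows.append({"test": label, "statistic": 0.0, "p": 1.0, "note": "degenerate"})
            return
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"test": label, "statistic": float(stat), "p": float(p), "note": "Welch t"})

    for field_name in ("age", "bmi", "madrs"):
        if field_name not in t.columns or t[field_name].isna().all():
            rows.append({"test": f"{field_name} (skipped)", "statistic": np.nan, "p": np.nan, "note": "field missing"})
            continue
        welch_row(f"{field_name} MDD vs nonMDD @ baseline", field_name, "baseline")
        if field_name in ("bmi", "madrs") and (t["timepoint"] == "post").any():
            welch_row(f"{field_name} MDD vs nonMDD @ post", field_name, "post")

    # prevalence: baseline diagnosis vs post-surgery current diagnosis
    base = t[t["timepoint"] == "baseline"]
    post = t[t["timepoint"] == "post"]
    n_mdd_base = int((base["group"] == "MDD").sum())
    n_non_base = int((base["group"] == "nonMDD").sum())
    rows.append(
        {
            "test": "MDD prevalence @ baseline (%)",
            "statistic": prevalence_pct(n_mdd_base, len(base)),
            "p": np.nan,
            "note": f"{n_mdd_base}/{len(base)}",
        }
    )
    if len(post):
        n_mdd_post = int(post_mdd_count) if post_mdd_count is not None else 0
        table2 = [[n_mdd_base, n_non_base], [n_mdd_post, len(post) - n_mdd_post]]
        rows.append(
            {
                "test": "MDD prevalence baseline vs post",
                "statistic": float(n_mdd_post),
                "p": fisher_2x2(table2),
                "note": "Fisher exact",
            }
        )

    if "sex" in t.columns and not t["sex"].isna().all():
        xt = pd.crosstab(base["group"], base["sex"])
        if xt.shape == (2, 2):
            rows.append(
                {"test": "sex by group @ baseline", "statistic": np.nan, "p": fisher_2x2(xt.to_numpy()), "note": "Fisher exact"}
            )
        else:
            rows.append({"test": "sex by group (skipped)", "statistic": np.nan, "p": np.nan, "note": "not 2x2"})
    else:
        rows.append({"test": "sex (skipped)", "statistic": np.nan, "p": np.nan, "note": "field missing"})

    if "bmi" in t.columns and not t["bmi"].isna().all():
        pairs = design.paired_patients()
        if len(pairs) >= 2:
            pre = [design.sample_of(p, "baseline") for p in pairs]
            pst = [design.sample_of(p, "post") for p in pairs]
            stat, p = stats.ttest_rel(
                t.loc[pre, "bmi"].to_numpy(dtype=float), t.loc[pst, "bmi"].to_numpy(dtype=float)
            )
            rows.append({"test": "BMI pre vs post (paired)", "statistic": float(stat), "p": float(p), "note": f"{len(pairs)} pairs"})

    return pd.DataFrame(rows)
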