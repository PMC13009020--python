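"""Outcome modelling: cohort summaries, screening, Cox OS/RFS and pCR logistics.

The primary imaging predictor throughout is the dichotomized quantitative BPE
grade (high 3/4 vs low 1/2) or, for treatment response, the change in
predicted grade across neoadjuvant chemotherapy.  Covariate screening keeps
only candidates univariately associated with the outcome at p < alpha, but
the primary predictor is always retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

logger = logging.getLogger(__name__)

SUBTYPES = ("HR+HER2-", "HR+HER2+", "HR-HER2+", "Triple negative")

#: columns expected in a cohort table (the data dictionary)
COHORT_COLUMNS = (
    "patient_id", "age_years", "menopausal_status", "race_ethnicity",
    "hr_status", "her2_status", "molecular_subtype", "tumor_stage",
    "histologic_grade", "node_positive", "nac", "radiologist_grade",
    "bpe_t0", "bpe_t3", "predicted_grade_t0", "predicted_grade_t3",
    "os_time", "rfs_time", "os_event", "rfs_event", "pcr",
)


@dataclass
class EffectEstimate:
    """A hazard or odds ratio with its Wald 95% CI (log scale) and p value."""

    effect_type: str  # "HR" | "OR"
    point: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    model_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


@dataclass
class CohortSummary:
    """Per-grade descriptive table plus pairwise comparisons against grade 1."""

    table: pd.DataFrame        # block, category, grade, count/pct or age stats
    comparisons: pd.DataFrame  # block, grade, p_value, stars


@dataclass
class ScreenResult:
    """Univariate screening decisions for one outcome."""

    outcome: str
    table: pd.DataFrame  # candidate, p_value, selected
    selected: list[str]


def derive_subtype(hr_status: int, her2_status: int) -> str:
    """Molecular subtype from hormone-receptor and HER2 positivity."""
    if hr_status and not her2_status:
        return "HR+HER2-"
    if hr_status and her2_status:
        return "HR+HER2+"
    if not hr_status and her2_status:
        return "HR-HER2+"
    return "Triple negative"


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check cohort invariants; raises on violation, returns the frame."""
    for col in ("os_time", "rfs_time"):
        if col in df and (df[col].dropna() < 0).any():
            raise ValueError(f"{col} contains negative times")
    for col in ("os_event", "rfs_event"):
        if col in df and not df[col].dropna().isin([0, 1]).all():
            raise ValueError(f"{col} must be 0/1")
    if {"hr_status", "her2_status", "molecular_subtype"}.issubset(df.columns):
        expected = [
            derive_subtype(hr, her2) for hr, her2 in zip(df["hr_status"], df["her2_status"])
        ]
        bad = df["molecular_subtype"].to_numpy() != np.asarray(expected)
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} rows have molecular_subtype inconsistent with HR/HER2 status"
            )
    return df


def reference_cohort_counts() -> pd.DataFrame:
    """Per-grade categorical counts of the reference multi-institutional cohort.

    Printed counts of the combined Duke-Breast-Cancer-MRI + I-SPY2 study
    population (n per radiologist BPE grade plus race/ethnicity, molecular
    subtype and menopausal-status blocks), used for summary-arithmetic checks.
    """
    with resources.files("bpemri.data").joinpath("reference_cohort_counts.csv").open() as fh:
        return pd.read_csv(fh)


def summarize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Column percentages of a per-grade counts table.

    Input schema matches :func:`reference_cohort_counts`: a ``cohort``/``n``
    row giving per-grade totals, then category rows.  Returns a long frame
    with block, category, grade, count and pct (count / grade n * 100).
    """
    grade_cols = [c for c in counts.columns if c.startswith("grade")]
    n_row = counts[(counts["block"] == "cohort") & (counts["category"] == "n")]
    if len(n_row) != 1:
        raise ValueError("counts table needs exactly one cohort/n row")
    totals = {g: int(n_row.iloc[0][g]) for g in grade_cols}
    rows = []
    for _, r in counts[counts["block"] != "cohort"].iterrows():
        for g in grade_cols:
            rows.append(
                {
                    "block": r["block"],
                    "category": r["category"],
                    "grade": int(g.removeprefix("grade")),
                    "count": int(r[g]),
                    "pct": 100.0 * r[g] / totals[g],
                }
            )
    return pd.DataFrame(rows)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def cohort_summary(
    df: pd.DataFrame,
    group_by: str = "radiologist_grade",
    categorical_blocks: Sequence[str] = ("race_ethnicity", "molecular_subtype", "menopausal_status"),
) -> CohortSummary:
    """Per-grade descriptive statistics with comparisons against the lowest grade.

    Age: mean +/- SD and median [IQR].  Categorical blocks: counts and column
    percentages.  Each higher grade is compared with the reference (lowest)
    grade: two-sample t test for age, chi-square on the block's contingency
    table for categoricals (Fisher's exact when the table is 2x2 with small
    expected counts).  Stars at 0.05 / 0.01 / 0.001.
    """
    if df.empty:
        raise ValueError("cohort is empty")
    grades = sorted(df[group_by].dropna().unique())
    ref = grades[0]
    rows = []
    for g in grades:
        sub = df[df[group_by] == g]
        n = len(sub)
        if n == 0:
            logger.warning("grade %s has no patients; omitted", g)
            continue
        age = sub["age_years"].dropna()
        rows.append(
            {"block": "cohort", "category": "n", "grade": g, "count": n, "pct": np.nan,
             "mean": np.nan, "sd": np.nan, "median": np.nan, "q1": np.nan, "q3": np.nan}
        )
        rows.append(
            {"block": "age", "category": "age_years", "grade": g, "count": len(age),
             "pct": np.nan, "mean": age.mean(), "sd": age.std(ddof=1),
             "median": age.median(), "q1": age.quantile(0.25), "q3": age.quantile(0.75)}
        )
        for block in categorical_blocks:
            vc = sub[block].value_counts()
            for cat, cnt in vc.items():
                rows.append(
                    {"block": block, "category": cat, "grade": g, "count": int(cnt),
                     "pct": 100.0 * cnt / n, "mean": np.nan, "sd": np.nan,
                     "median": np.nan, "q1": np.nan, "q3": np.nan}
                )
    table = pd.DataFrame(rows)

    comp_rows = []
    if len(grades) > 1:
        ref_df = df[df[group_by] == ref]
        for g in grades[1:]:
            sub = df[df[group_by] == g]
            t_res = stats.ttest_ind(ref_df["age_years"].dropna(), sub["age_years"].dropna())
            comp_rows.append(
                {"block": "age", "grade": g, "p_value": float(t_res.pvalue),
                 "stars": _stars(float(t_res.pvalue))}
            )
            for block in categorical_blocks:
                ct = pd.crosstab(
                    df.loc[df[group_by].isin([ref, g]), group_by],
                    df.loc[df[group_by].isin([ref, g]), block],
                )
                ct = ct.loc[:, ct.sum(axis=0) > 0]
                if ct.shape == (2, 2):
                    expected = stats.contingency.expected_freq(ct.to_numpy())
                    if (expected < 5).any():
                        p = float(stats.fisher_exact(ct.to_numpy())[1])
                    else:
                        p = float(stats.chi2_contingency(ct.to_numpy())[1])
                elif ct.shape[0] == 2 and ct.shape[1] >= 2:
                    p = float(stats.chi2_contingency(ct.to_numpy())[1])
                else:
                    p = np.nan
                comp_rows.append(
                    {"block": block, "grade": g, "p_value": p,
                     "stars": _stars(p) if np.isfinite(p) else ""}
                )
    comparisons = pd.DataFrame(comp_rows, columns=["block", "grade", "p_value", "stars"])
    return CohortSummary(table=table, comparisons=comparisons)


# ---------------------------------------------------------------------------
# regression models

_OUTCOME_FIELDS = {"OS": ("os_time", "os_event"), "RFS": ("rfs_time", "rfs_event")}


def _design(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Numeric design matrix: categoricals one-hot encoded dropping the first level."""
    X = pd.DataFrame(index=df.index)
    for col in columns:
        s = df[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[col] = pd.to_numeric(s)
    return X.astype(float)


def _cox_fit(df: pd.DataFrame, duration: str, event: str, columns: Sequence[str]) -> CoxPHFitter:
    X = _design(df, columns)
    data = pd.concat([df[[duration, event]].astype(float), X], axis=1).dropna()
    cph = CoxPHFitter()
    cph.fit(data, duration_col=duration, event_col=event)
    return cph


def fit_cox(
    df: pd.DataFrame,
    outcome: str,
    predictor: str = "bpe_high",
    covariates: Sequence[str] = (),
) -> EffectEstimate:
    """Cox proportional-hazards fit; reports the predictor's adjusted HR.

    Partial likelihood with Efron tie handling (lifelines' default); the HR
    and its 95% CI are exp of the coefficient and of its Wald interval.
    """
    if outcome not in _OUTCOME_FIELDS:
        raise ValueError("outcome must be OS or RFS")
    duration, event = _OUTCOME_FIELDS[outcome]
    sub = df.dropna(subset=[duration, event, predictor])
    if sub[event].sum() < 1:
        raise ValueError("no events observed; Cox model is not estimable")
    if sub[predictor].nunique() < 2:
        raise ValueError(f"predictor {predictor!r} has a single level")
    try:
        cph = _cox_fit(sub, duration, event, [predictor, *covariates])
    except Exception as exc:  # lifelines raises ConvergenceError and warnings
        raise RuntimeError(f"Cox fit failed for {outcome}: {exc}") from exc
    s = cph.summary.loc[predictor]
    return EffectEstimate(
        effect_type="HR",
        point=float(s["exp(coef)"]),
        ci_low=float(s["exp(coef) lower 95%"]),
        ci_high=float(s["exp(coef) upper 95%"]),
        p_value=float(s["p"]),
        n_used=int(cph._n_examples),
        model_terms=list(cph.summary.index),
    )


def fit_pcr_logistic(
    df: pd.DataFrame,
    predictor: str,
    covariates: Sequence[str] = (),
    outcome: str = "pcr",
) -> EffectEstimate:
    """Maximum-likelihood logistic fit; reports the predictor's adjusted OR.

    The OR and its 95% CI are exp of the coefficient and of its Wald
    interval.  Quasi-separation surfaces as a RuntimeError with the
    underlying diagnostic.
    """
    sub = df.dropna(subset=[outcome, predictor])
    y = sub[outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError("outcome has a single level")
    if sub[predictor].nunique() < 2:
        raise ValueError(f"predictor {predictor!r} has a single level")
    X = sm.add_constant(_design(sub, [predictor, *covariates]), has_constant="add")
    try:
        res = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-12, maxiter=200)
    except Exception as exc:
        raise RuntimeError(f"logistic fit failed ({exc})") from exc
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("logistic fit did not converge (quasi-separation)")
    if not np.all(np.isfinite(res.bse)) or np.any(np.abs(res.params) > 15):
        raise RuntimeError("logistic fit: degenerate coefficients (quasi-separation)")
    coef = float(res.params[predictor])
    se = float(res.bse[predictor])
    z = stats.norm.ppf(0.975)
    return EffectEstimate(
        effect_type="OR",
        point=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        p_value=float(res.pvalues[predictor]),
        n_used=int(res.nobs),
        model_terms=list(X.columns.drop("const")),
    )


def univariate_screen(
    df: pd.DataFrame,
    outcome: str,
    candidates: Sequence[str],
    alpha: float = 0.05,
    primary: Optional[str] = None,
) -> ScreenResult:
    """One-covariate fits per candidate; keep those with p < alpha.

    OS/RFS candidates are screened with single-covariate Cox fits, pCR with
    single-covariate logistic fits; the p value is the likelihood-ratio test
    of the candidate (well calibrated under the null for multi-level
    categoricals too).  The primary predictor is always retained regardless
    of its p value.  Non-converging candidates are logged and excluded.
    """
    rows = []
    for cand in candidates:
        try:
            if outcome in _OUTCOME_FIELDS:
                duration, event = _OUTCOME_FIELDS[outcome]
                sub = df.dropna(subset=[duration, event, cand])
                cph = _cox_fit(sub, duration, event, [cand])
                p = float(cph.log_likelihood_ratio_test().p_value)
            elif outcome == "pCR":
                sub = df.dropna(subset=["pcr", cand])
                y = sub["pcr"].astype(float)
                X = sm.add_constant(_design(sub, [cand]), has_constant="add")
                res = sm.Logit(y, X).fit(disp=0)
                p = float(res.llr_pvalue)
            else:
                raise ValueError("outcome must be OS, RFS or pCR")
        except ValueError:
            raise
        except Exception as exc:
            logger.warning("screening candidate %r failed to converge (%s); excluded", cand, exc)
            rows.append({"candidate": cand, "p_value": np.nan, "selected": False})
            continue
        rows.append({"candidate": cand, "p_value": p, "selected": bool(p < alpha)})
    table = pd.DataFrame(rows, columns=["candidate", "p_value", "selected"])
    selected = table.loc[table["selected"], "candidate"].tolist()
    if primary is not None and primary not in selected:
        selected = [primary] + [c for c in selected if c != primary]
    return ScreenResult(outcome=outcome, table=table, selected=selected)


def stratified_analysis(
    df: pd.DataFrame,
    strata: Mapping[str, pd.Series],
    model_fn: Callable[[pd.DataFrame], EffectEstimate],
) -> pd.DataFrame:
    """Refit a model within each stratum; small/degenerate strata are flagged.

    ``strata`` maps a stratum name to a boolean row selector; the caller's
    ``model_fn`` must already omit the stratifying covariate from its
    adjustment set.  Returns one row per stratum with the effect estimate or
    ``estimable = False``.
    """
    rows = []
    for name, sel in strata.items():
        sub = df[np.asarray(sel, dtype=bool)]
        row = {"stratum": name, "n": len(sub), "estimable": False,
               "point": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan}
        try:
            est = model_fn(sub)
            row.update(
                estimable=True, point=est.point, ci_low=est.ci_low,
                ci_high=est.ci_high, p_value=est.p_value, n=est.n_used,
            )
        except (ValueError, RuntimeError) as exc:
            logger.warning("stratum %r not estimable: %s", name, exc)
        rows.append(row)
    return pd.DataFrame(rows)


def age_median_strata(df: pd.DataFrame, col: str = "age_years") -> dict[str, pd.Series]:
    """Median split on age: 'age_gt_median' vs 'age_le_median'."""
    med = df[col].median()
    return {"age_gt_median": df[col] > med, "age_le_median": df[col] <= med}
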