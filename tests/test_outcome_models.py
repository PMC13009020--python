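"""Cohort summaries, screening, Cox and logistic fits against written-likelihood oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from bpemri.outcome_models import (
    age_median_strata,
    cohort_summary,
    derive_subtype,
    fit_cox,
    fit_pcr_logistic,
    reference_cohort_counts,
    stratified_analysis,
    summarize_counts,
    univariate_screen,
    validate_cohort,
)
from bpemri.synthetic_data import CohortSpec, generate_cohort


def cox_partial_loglik(beta, times, events, x):
    """Written-out partial log-likelihood (no ties in these datasets)."""
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    ll = 0.0
    for i in range(len(times)):
        if events[i]:
            risk = x[i:] * beta
            ll += x[i] * beta - np.log(np.sum(np.exp(risk)))
    return ll


def logistic_loglik(params, y, X):
    eta = X @ params
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


@pytest.fixture(scope="module")
def cohort300():
    return generate_cohort(CohortSpec(n=300, seed=11)).cohort


class TestCohortSummary:
    def test_reference_counts_percentages(self):
        pct = summarize_counts(reference_cohort_counts())
        g4_pre = pct[(pct["category"] == "Premenopausal") & (pct["grade"] == 4)]
        assert g4_pre["pct"].iloc[0] == pytest.approx(72.73, abs=0.01)
        g1_white = pct[(pct["category"] == "White") & (pct["grade"] == 1)]
        assert g1_white["pct"].iloc[0] == pytest.approx(71.13, abs=0.01)

    def test_reference_cohort_total(self):
        counts = reference_cohort_counts()
        n_row = counts[(counts["block"] == "cohort") & (counts["category"] == "n")].iloc[0]
        assert int(n_row[["grade1", "grade2", "grade3", "grade4"]].sum()) == 1074

    def test_percentages_sum_to_100_within_rounding(self, cohort300):
        summ = cohort_summary(cohort300)
        cat = summ.table[summ.table["block"].isin(
            ["race_ethnicity", "molecular_subtype", "menopausal_status"])]
        sums = cat.groupby(["block", "grade"])["pct"].sum()
        assert np.allclose(sums, 100.0, atol=0.01)

    def test_age_block_and_comparisons_present(self, cohort300):
        summ = cohort_summary(cohort300)
        age = summ.table[summ.table["block"] == "age"]
        assert set(age["grade"]) == {1, 2, 3, 4}
        assert np.isfinite(age["mean"]).all() and (age["q1"] <= age["median"]).all()
        assert not summ.comparisons.empty
        assert set(summ.comparisons["grade"]) == {2, 3, 4}

    def test_single_grade_cohort_suppresses_comparisons(self, cohort300):
        one = cohort300[cohort300["radiologist_grade"] == 2]
        summ = cohort_summary(one)
        assert summ.comparisons.empty


def test_subtype_derivation_and_validation(cohort300):
    assert derive_subtype(1, 0) == "HR+HER2-"
    assert derive_subtype(0, 0) == "Triple negative"
    validate_cohort(cohort300)
    broken = cohort300.copy()
    broken.loc[broken.index[0], "molecular_subtype"] = "Triple negative"
    broken.loc[broken.index[0], "hr_status"] = 1
    broken.loc[broken.index[0], "her2_status"] = 0
    with pytest.raises(ValueError):
        validate_cohort(broken)


class TestCox:
    def test_coefficient_matches_independent_maximizer(self):
        rng = np.random.default_rng(21)
        n = 40
        x = rng.binomial(1, 0.5, size=n).astype(float)
        times = rng.exponential(1.0 / np.exp(np.log(0.6) * x))
        events = np.ones(n)
        df = pd.DataFrame(
            {"os_time": times, "os_event": events, "bpe_high": x}
        )
        est = fit_cox(df, "OS", "bpe_high")
        res = optimize.minimize_scalar(
            lambda b: -cox_partial_loglik(b, times, events, x), bounds=(-5, 5),
            method="bounded", options={"xatol": 1e-10},
        )
        assert np.log(est.point) == pytest.approx(res.x, abs=1e-6)

    def test_ci_is_exp_of_coefficient_interval(self):
        syn = generate_cohort(CohortSpec(n=400, seed=3))
        est = fit_cox(syn.cohort, "OS", "bpe_high", ["age_years"])
        assert est.effect_type == "HR"
        assert est.ci_low <= est.point <= est.ci_high
        # Wald symmetry on the log scale
        assert np.log(est.point) - np.log(est.ci_low) == pytest.approx(
            np.log(est.ci_high) - np.log(est.point), rel=1e-6
        )

    def test_all_censored_rejected(self):
        df = pd.DataFrame(
            {"os_time": [1.0, 2.0, 3.0, 4.0], "os_event": [0, 0, 0, 0],
             "bpe_high": [0, 1, 0, 1]}
        )
        with pytest.raises(ValueError):
            fit_cox(df, "OS", "bpe_high")


class TestPcrLogistic:
    def test_unadjusted_2x2_equals_cross_product_ratio(self):
        # a=10 drop&pcr, b=5 drop&no, c=4 nodrop&pcr, d=20 nodrop&no -> OR 10
        drop = np.repeat([1, 1, 0, 0], [10, 5, 4, 20])
        pcr = np.repeat([1, 0, 1, 0], [10, 5, 4, 20])
        df = pd.DataFrame({"pcr": pcr, "drop_in_grade": drop})
        est = fit_pcr_logistic(df, "drop_in_grade")
        assert est.point == pytest.approx((10 * 20) / (5 * 4), abs=1e-12)

    def test_coefficient_matches_independent_maximizer(self):
        rng = np.random.default_rng(33)
        n = 50
        x = rng.binomial(1, 0.5, size=n).astype(float)
        p = 1 / (1 + np.exp(-(-1.0 + 1.2 * x)))
        y = rng.binomial(1, p).astype(float)
        df = pd.DataFrame({"pcr": y, "drop_in_grade": x})
        est = fit_pcr_logistic(df, "drop_in_grade")
        X = np.column_stack([np.ones(n), x])
        res = optimize.minimize(
            lambda b: -logistic_loglik(b, y, X), x0=np.zeros(2), method="BFGS",
            options={"gtol": 1e-12},
        )
        assert np.log(est.point) == pytest.approx(res.x[1], abs=1e-6)

    def test_single_level_predictor_rejected(self):
        df = pd.DataFrame({"pcr": [0, 1, 0, 1], "drop_in_grade": [1, 1, 1, 1]})
        with pytest.raises(ValueError):
            fit_pcr_logistic(df, "drop_in_grade")


class TestScreening:
    def test_empty_candidates_keep_only_primary(self, cohort300):
        screen = univariate_screen(cohort300, "OS", [], primary="bpe_high")
        assert screen.selected == ["bpe_high"]

    def test_strong_covariate_always_selected(self):
        rng = np.random.default_rng(5)
        n = 500
        x = rng.binomial(1, 0.5, size=n)
        times = rng.exponential(1.0 / np.exp(1.0 * x))
        df = pd.DataFrame({"os_time": times, "os_event": np.ones(n), "strong": x})
        screen = univariate_screen(df, "OS", ["strong"])
        assert screen.selected == ["strong"]

    def test_categorical_candidate_handled(self, cohort300):
        screen = univariate_screen(cohort300, "OS", ["menopausal_status"])
        assert np.isfinite(screen.table["p_value"]).all()


class TestStratified:
    def test_identical_strata_give_identical_estimates(self, cohort300):
        strata = {"a": pd.Series(True, index=cohort300.index),
                  "b": pd.Series(True, index=cohort300.index)}
        res = stratified_analysis(cohort300, strata, lambda df: fit_cox(df, "OS", "bpe_high"))
        assert res.loc[0, "point"] == res.loc[1, "point"]

    def test_median_age_split_balanced(self, cohort300):
        strata = age_median_strata(cohort300)
        sizes = [int(np.asarray(v).sum()) for v in strata.values()]
        assert abs(sizes[0] - sizes[1]) <= 1
        assert sum(sizes) == len(cohort300)

    def test_degenerate_stratum_flagged_not_fatal(self, cohort300):
        strata = {"tiny": pd.Series(False, index=cohort300.index)}
        res = stratified_analysis(cohort300, strata, lambda df: fit_cox(df, "OS", "bpe_high"))
        assert not res.loc[0, "estimable"]
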