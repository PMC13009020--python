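"""Threshold calibration, grade models and the longitudinal paired test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bpemri.calibration import (
    assign_grade,
    dichotomy_auc,
    fit_grade_model,
    grade_change,
    optimize_threshold,
    paired_change_test,
    spearman_rho,
)
from bpemri.synthetic_data import CohortSpec, generate_cohort


def rank_average_ties(v):
    """Exhaustive average-rank computation (independent of scipy's)."""
    v = np.asarray(v, dtype=float)
    ranks = np.empty(len(v))
    for i, x in enumerate(v):
        less = np.sum(v < x)
        equal = np.sum(v == x)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def concordance_auc(scores, labels):
    """Exhaustive pair counting: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    num = 0.0
    for p, q in itertools.product(pos, neg):
        num += 1.0 if p > q else (0.5 if p == q else 0.0)
    return num / (len(pos) * len(neg))


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [30, 20, 10]) == pytest.approx(-1.0)

    def test_tied_ranks_match_exhaustive_rank_formula(self):
        x = [1.0, 2.0, 2.0, 4.0]
        y = [1.0, 3.0, 2.0, 4.0]
        rx, ry = rank_average_ties(x), rank_average_ties(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_is_signalled(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [1, 2])


class TestDichotomyAUC:
    def test_separable_and_tied_limits(self):
        grades = [1, 1, 3, 4]
        assert dichotomy_auc([0.1, 0.2, 0.8, 0.9], grades, "12_v_34") == 1.0
        assert dichotomy_auc([0.5, 0.5, 0.5, 0.5], grades, "12_v_34") == 0.5

    def test_matches_exhaustive_concordance_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = int(rng.integers(4, 13))
            grades = rng.integers(1, 5, size=n)
            if (grades >= 3).all() or (grades < 3).all():
                continue
            scores = np.round(rng.uniform(0, 1, size=n), 1)  # rounding forces ties
            auc = dichotomy_auc(scores, grades, "12_v_34")
            assert auc == pytest.approx(
                concordance_auc(scores, (grades >= 3).astype(int)), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(0.01, 1, size=30)
        grades = rng.integers(1, 5, size=30)
        base = dichotomy_auc(scores, grades, "1_v_234")
        for f in (np.log, np.sqrt, lambda x: 100 * x - 3):
            assert dichotomy_auc(f(scores), grades, "1_v_234") == pytest.approx(base)

    def test_empty_class_is_an_error(self):
        with pytest.raises(ValueError):
            dichotomy_auc([0.1, 0.2], [1, 2], "12_v_34")


class TestOptimizeThreshold:
    def test_recovers_generative_threshold(self):
        syn = generate_cohort(CohortSpec(n=300, generative_threshold=55.0, seed=0))
        curve = optimize_threshold(syn.sweep, syn.cohort)
        assert abs(curve.optimal_k - 55.0) <= 5.0
        at_opt = curve.at_optimum()
        assert 0.5 <= at_opt["auc_12_v_34"] <= 1.0

    def test_independent_grades_give_near_zero_rho(self):
        rng = np.random.default_rng(4)
        n = 400
        syn = generate_cohort(CohortSpec(n=n, seed=4))
        shuffled = syn.cohort.copy()
        shuffled["radiologist_grade"] = rng.permutation(shuffled["radiologist_grade"].to_numpy())
        curve = optimize_threshold(syn.sweep, shuffled)
        assert np.nanmax(np.abs(curve.table["rho"])) < 3.0 / np.sqrt(n)

    def test_single_threshold_grid_returned(self):
        syn = generate_cohort(CohortSpec(n=50, threshold_grid=(55.0,), seed=1))
        curve = optimize_threshold(syn.sweep, syn.cohort)
        assert curve.optimal_k == 55.0

    def test_all_equal_grades_rejected(self):
        syn = generate_cohort(CohortSpec(n=30, seed=2))
        flat = syn.cohort.copy()
        flat["radiologist_grade"] = 2
        with pytest.raises(ValueError):
            optimize_threshold(syn.sweep, flat)


class TestGradeModel:
    def test_separable_cohort_reproduces_every_grade(self):
        grades = np.repeat([1, 2, 3, 4], 10)
        bpe = grades / 4.0
        model = fit_grade_model(bpe, grades, threshold_k=55.0)
        cuts = model.cutpoints_4level
        for lo, hi, c in zip((0.25, 0.5, 0.75), (0.5, 0.75, 1.0), cuts):
            assert lo < c < hi  # strictly between consecutive grade values
        reassigned = [assign_grade(model, b) for b in bpe]
        np.testing.assert_array_equal(reassigned, grades)
        groups = [assign_grade(model, b, levels=2) for b in bpe]
        assert groups == ["low"] * 20 + ["high"] * 20

    def test_two_level_cutpoint_recovery_under_noise(self):
        rng = np.random.default_rng(6)
        true_cut = 0.30
        bpe = rng.uniform(0, 0.6, size=400)
        grades = np.where(bpe + rng.normal(0, 0.02, size=400) >= true_cut, 3, 2)
        if len(np.unique(grades)) < 2:
            pytest.skip("degenerate draw")
        model = fit_grade_model(bpe, grades, four_level=False)
        assert model.cutpoints_2level == pytest.approx(true_cut, abs=0.05)

    def test_missing_grades_rejected(self):
        with pytest.raises(ValueError):
            fit_grade_model([0.1, 0.2, 0.3], [2, 2, 2])
        with pytest.raises(ValueError):
            fit_grade_model([0.1, 0.2, 0.3, 0.4], [1, 2, 3, 3], four_level=True)

    def test_assignment_boundaries_closed_on_the_right(self):
        from bpemri.calibration import GradeModel

        model = GradeModel(cutpoints_2level=0.3, cutpoints_4level=np.array([0.1, 0.3, 0.5]))
        assert assign_grade(model, 0.05) == 1
        assert assign_grade(model, 0.95) == 4
        assert assign_grade(model, 0.3) == 3  # exactly at a cutpoint -> higher grade
        assert assign_grade(model, 0.3, levels=2) == "high"
        vals = np.linspace(0, 1, 50)
        assigned = [assign_grade(model, v) for v in vals]
        assert (np.diff(assigned) >= 0).all()


def test_grade_change_direction():
    assert grade_change(3, 1) == "drop"
    assert grade_change(2, 2) == "stable"
    assert grade_change(1, 3) == "increase"
    with pytest.raises(ValueError):
        grade_change(0, 2)


class TestPairedChangeTest:
    def test_identical_pairs_give_zero_statistic(self):
        x = [0.1, 0.2, 0.3]
        with pytest.warns(UserWarning):
            res = paired_change_test(x, x)
        assert res.loc[0, "t_statistic"] == 0.0
        assert res.loc[0, "mean_diff"] == 0.0

    def test_matches_closed_form_t(self):
        t0 = np.zeros(3)
        t3 = np.array([0.1, 0.2, 0.3])
        res = paired_change_test(t0, t3)
        d = t3 - t0
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert res.loc[0, "t_statistic"] == pytest.approx(expected_t, abs=1e-12)
        assert res.loc[0, "p_value"] == pytest.approx(
            2 * stats.t.sf(abs(expected_t), df=2), abs=1e-12
        )

    def test_zero_variance_nonzero_mean_raises(self):
        with pytest.raises(ValueError):
            paired_change_test([0.1, 0.1], [0.3, 0.3])

    def test_stratified_output_one_row_per_stratum(self):
        rng = np.random.default_rng(3)
        t0 = rng.uniform(0.1, 0.5, size=40)
        t3 = t0 - 0.05 + rng.normal(0, 0.02, size=40)
        strata = np.repeat([1, 2, 3, 4], 10)
        res = paired_change_test(t0, t3, strata=strata)
        assert len(res) == 4
        assert (res["mean_diff"] < 0).all()

    def test_power_against_noncentral_t_prediction(self):
        """A true mean drop delta at n=50 rejects at the rate the noncentral t predicts."""
        rng = np.random.default_rng(77)
        n, delta, sd, reps = 50, 0.05, 0.12, 400
        rejections = 0
        for _ in range(reps):
            t0 = rng.uniform(0.2, 0.6, size=n)
            t3 = t0 - delta + rng.normal(0, sd, size=n)
            res = paired_change_test(t0, t3)
            rejections += res.loc[0, "p_value"] < 0.05
        ncp = delta / (sd / np.sqrt(n))
        crit = stats.t.ppf(0.975, df=n - 1)
        predicted = stats.nct.sf(crit, df=n - 1, nc=ncp) + stats.nct.cdf(-crit, df=n - 1, nc=ncp)
        se = np.sqrt(predicted * (1 - predicted) / reps)
        assert rejections / reps == pytest.approx(predicted, abs=max(4 * se, 0.02))
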