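"""Calibration of the enhancement threshold against radiologist BPE grades.

Radiologists grade BPE on an ordinal 1-4 scale (minimal / mild / moderate /
marked).  The quantitative statistic depends on the enhancement threshold k;
the calibrated k maximizes the Spearman rank correlation between quantitative
BPE and the ordinal grade across the cohort.  Grade-separation quality is
summarized by ROC AUCs of the three cumulative dichotomies (1 vs 2-4,
1-2 vs 3-4, 1-3 vs 4), and monotone cutpoints on BPE reproduce a predicted
grade for downstream outcome models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

SPLITS = ("1_v_234", "12_v_34", "123_v_4")
#: minimum grade of the positive (high) class for each dichotomy
_SPLIT_MIN_HIGH = {"1_v_234": 2, "12_v_34": 3, "123_v_4": 4}


@dataclass
class ThresholdCurve:
    """Per-threshold Spearman rho and dichotomy AUCs, with the optimum.

    ``optimal_k`` attains the maximal rho; ties break to the smallest k.
    """

    table: pd.DataFrame  # columns: threshold_k, rho, auc_1_v_234, auc_12_v_34, auc_123_v_4
    optimal_k: float

    @property
    def thresholds(self) -> np.ndarray:
        return self.table["threshold_k"].to_numpy()

    def at_optimum(self) -> pd.Series:
        return self.table.loc[self.table["threshold_k"] == self.optimal_k].iloc[0]


@dataclass
class GradeModel:
    """Monotone BPE cutpoints mapping quantitative BPE to ordinal grades.

    ``cutpoints_2level`` separates predicted low grade (1/2) from high (3/4);
    ``cutpoints_4level`` are three non-decreasing cutpoints for the full 1-4
    scale.  Assignment is closed on the right: BPE equal to a cutpoint gets
    the higher grade.
    """

    cutpoints_2level: float
    cutpoints_4level: Optional[np.ndarray] = None
    threshold_k: Optional[float] = None
    isotonic_adjusted: bool = False

    def __post_init__(self) -> None:
        if self.cutpoints_4level is not None:
            c = np.asarray(self.cutpoints_4level, dtype=float)
            if c.shape != (3,):
                raise ValueError("4-level model needs exactly 3 cutpoints")
            if np.any(np.diff(c) < 0):
                raise ValueError("4-level cutpoints must be non-decreasing")
            self.cutpoints_4level = c


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Raises on constant input, where the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def dichotomy_auc(bpe: Sequence[float], grades: Sequence[int], split: str) -> float:
    """ROC AUC of the BPE score for the high-grade class of ``split``.

    Equal to the concordance probability P(score_high > score_low) with ties
    counted 1/2, and therefore invariant under any strictly monotone transform
    of the scores.
    """
    if split not in _SPLIT_MIN_HIGH:
        raise ValueError(f"split must be one of {SPLITS}, got {split!r}")
    bpe = np.asarray(bpe, dtype=float)
    grades = np.asarray(grades)
    labels = (grades >= _SPLIT_MIN_HIGH[split]).astype(int)
    if labels.min() == labels.max():
        raise ValueError(f"split {split}: one class is empty")
    return float(roc_auc_score(labels, bpe))


def optimize_threshold(
    sweep: pd.DataFrame,
    grades: pd.DataFrame,
    grid: Optional[Sequence[float]] = None,
) -> ThresholdCurve:
    """Sweep the enhancement threshold and maximize Spearman rho against grades.

    ``sweep`` is the long-format BPE table (patient_id, threshold_k,
    bpe_value); ``grades`` maps patient_id to radiologist_grade.  Every
    patient must have a BPE value at every grid point.  AUCs for the three
    cumulative dichotomies are computed per threshold where both classes are
    present.
    """
    merged = sweep.merge(grades[["patient_id", "radiologist_grade"]], on="patient_id")
    if merged["radiologist_grade"].nunique() < 2:
        raise ValueError("need >= 2 distinct grades to calibrate the threshold")
    if grid is None:
        grid = np.sort(merged["threshold_k"].unique())
    rows = []
    for k in grid:
        sub = merged[merged["threshold_k"] == k]
        if sub.empty:
            raise ValueError(f"no BPE values at threshold {k}")
        bpe = sub["bpe_value"].to_numpy()
        g = sub["radiologist_grade"].to_numpy()
        try:
            rho = spearman_rho(bpe, g)
        except ValueError:
            rho = np.nan  # constant BPE at this threshold (e.g. everyone 0)
        row = {"threshold_k": float(k), "rho": rho}
        for split in SPLITS:
            try:
                row[f"auc_{split}"] = dichotomy_auc(bpe, g, split)
            except ValueError:
                row[f"auc_{split}"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    if table["rho"].isna().all():
        raise ValueError("Spearman correlation undefined at every threshold")
    best = table["rho"].max()
    optimal_k = float(table.loc[table["rho"] == best, "threshold_k"].min())
    return ThresholdCurve(table=table, optimal_k=optimal_k)


def _youden_cutpoint(scores: np.ndarray, labels: np.ndarray) -> float:
    """Cutpoint maximizing Youden's J = sensitivity + specificity - 1.

    Candidate cutpoints are midpoints between consecutive distinct scores
    (plus one below the minimum), so separable classes yield a cutpoint
    strictly between the two groups.  Prediction rule: score >= cutpoint is
    positive.  Ties in J break to the smallest cutpoint.
    """
    uniq = np.unique(scores)
    candidates = np.concatenate(([uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]))
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_j, best_c = -np.inf, candidates[0]
    for c in candidates:
        pred = scores >= c
        tpr = np.count_nonzero(pred & (labels == 1)) / n_pos
        fpr = np.count_nonzero(pred & (labels == 0)) / n_neg
        j = tpr - fpr
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return float(best_c)


def fit_grade_model(
    bpe: Sequence[float],
    grades: Sequence[int],
    threshold_k: Optional[float] = None,
    four_level: bool = True,
) -> GradeModel:
    """Fit Youden-optimal BPE cutpoints for the 2-level and 4-level gradings.

    The 2-level cutpoint dichotomizes grade 1/2 vs 3/4.  The 4-level
    cutpoints come from the three cumulative dichotomies (>= 2, >= 3, = 4),
    projected to be non-decreasing by a running maximum (logged when the
    repair changes anything).  Youden's J is used rather than a logistic
    probability crossing: for a single monotone covariate both criteria rank
    cutpoints identically, and J stays well-defined under complete separation.
    """
    bpe = np.asarray(bpe, dtype=float)
    grades = np.asarray(grades, dtype=int)
    present = np.unique(grades)
    if not np.all(np.isin(present, [1, 2, 3, 4])):
        raise ValueError("grades must lie in 1..4")
    if len(present) < 2:
        raise ValueError("need >= 2 distinct grades to fit cutpoints")
    high = (grades >= 3).astype(int)
    if high.min() == high.max():
        raise ValueError("both grade groups (1/2 and 3/4) must be present")
    cut2 = _youden_cutpoint(bpe, high)
    cut4 = None
    adjusted = False
    if four_level:
        if len(present) < 4:
            raise ValueError("4-level fit requires all four grades present")
        cuts = [
            _youden_cutpoint(bpe, (grades >= g).astype(int)) for g in (2, 3, 4)
        ]
        repaired = np.maximum.accumulate(cuts)
        adjusted = bool(np.any(repaired != cuts))
        if adjusted:
            logger.info("isotonic repair applied to 4-level cutpoints: %s -> %s", cuts, repaired)
        cut4 = repaired
    return GradeModel(
        cutpoints_2level=cut2,
        cutpoints_4level=cut4,
        threshold_k=threshold_k,
        isotonic_adjusted=adjusted,
    )


def assign_grade(model: GradeModel, bpe: float, levels: int = 4):
    """Map a BPE value to a predicted grade; monotone and closed on the right."""
    if levels == 2:
        return "high" if bpe >= model.cutpoints_2level else "low"
    if levels == 4:
        if model.cutpoints_4level is None:
            raise ValueError("model has no 4-level cutpoints")
        return int(np.count_nonzero(model.cutpoints_4level <= bpe) + 1)
    raise ValueError("levels must be 2 or 4")


def grade_change(grade_t0: int, grade_t3: int) -> str:
    """Direction of the predicted-grade change across NAC: drop/stable/increase."""
    for g in (grade_t0, grade_t3):
        if g not in (1, 2, 3, 4):
            raise ValueError(f"grade {g} outside 1..4")
    d = grade_t3 - grade_t0
    return "drop" if d < 0 else ("increase" if d > 0 else "stable")


def paired_change_test(
    bpe_t0: Sequence[float],
    bpe_t3: Sequence[float],
    strata: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Paired t test of post-NAC minus pre-NAC BPE, optionally per stratum.

    Returns one row per stratum (or a single "all" row) with the t statistic,
    two-sided p value, mean difference and n.  Identical pairs everywhere give
    t = 0, p = 1 with a warning; zero variance around a nonzero mean raises,
    since the statistic is unbounded there.
    """
    t0 = np.asarray(bpe_t0, dtype=float)
    t3 = np.asarray(bpe_t3, dtype=float)
    if t0.shape != t3.shape:
        raise ValueError("paired vectors must have equal length")
    if strata is None:
        strata = np.repeat("all", len(t0))
    strata = np.asarray(strata)
    rows = []
    for s in pd.unique(strata):
        sel = strata == s
        d = t3[sel] - t0[sel]
        if len(d) < 2:
            raise ValueError(f"stratum {s!r}: need >= 2 pairs")
        if np.ptp(d) == 0:
            if d[0] == 0:
                warnings.warn(f"stratum {s!r}: all differences are zero; t = 0")
                tstat, p = 0.0, 1.0
            else:
                raise ValueError(f"stratum {s!r}: zero variance around nonzero mean difference")
        else:
            res = stats.ttest_rel(t3[sel], t0[sel])
            tstat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {"stratum": s, "n": int(sel.sum()), "mean_diff": float(d.mean()),
             "t_statistic": tstat, "p_value": p}
        )
    return pd.DataFrame(rows)
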