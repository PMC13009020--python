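"""Synthetic DCE phantoms and cohort simulators with known ground truth.

Phantoms are two-ellipsoid "breast" volumes on a regular grid.  A designed
fraction of breast voxels is FGT and a designed fraction of FGT voxels
enhances at a designed amplitude, so the volume-based BPE is known exactly by
construction (enhancing fraction x FGT fraction) for every threshold below
the amplitude.  Noise is additive Gaussian on signal intensities, applied
before the enhancement ratio.

Cohorts emulate the statistical structure the downstream analysis assumes.
Each patient carries a parametric FGT enhancement-amplitude distribution
(Gaussian with patient-specific mean and spread) and an FGT/breast volume
ratio, giving an analytic threshold sweep

    BPE_i(k) = r_i * P(amplitude_i >= k).

The ordinal radiologist grade is a cutpoint binning of BPE at the generative
threshold k*, plus symmetric adjacent-grade misclassification noise
(emulating interobserver variability).  Survival times follow a
proportional-hazards exponential model on the dichotomized grade with
administrative censoring solved for a target event rate; pCR follows a
logistic model on the change in predicted grade across NAC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from bpemri.imaging_io import DCEStudy, MaskSet
from bpemri.outcome_models import derive_subtype

#: per-grade prevalences of the reference cohort (44% / 28% / 19% / 9%)
DEFAULT_GRADE_PREVALENCE = (0.44, 0.28, 0.19, 0.09)

#: race/ethnicity sampling probabilities, reference-cohort proportions
RACE_PROBS = {
    "White": 0.707,
    "Black or African American": 0.198,
    "Asian": 0.022,
    "Hispanic or Latino": 0.038,
    "American Indian or Alaska Native": 0.021,
    "Native Hawaiian or Pacific Islander": 0.004,
    "Multi-racial": 0.010,
}

SUBTYPE_PROBS = {
    "HR+HER2-": 0.603,
    "HR+HER2+": 0.115,
    "HR-HER2+": 0.070,
    "Triple negative": 0.212,
}


@dataclass
class PhantomSpec:
    """Geometry, tissue fractions and signal model of one DCE phantom."""

    shape: tuple[int, int, int] = (40, 24, 16)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    #: breast ellipsoids as (center, radii) in voxel coordinates; defaults are
    #: two ellipsoids separated along axis 0 (the laterality axis)
    ellipsoids: tuple = (
        ((10.0, 12.0, 8.0), (8.0, 9.0, 6.0)),
        ((30.0, 12.0, 8.0), (8.0, 9.0, 6.0)),
    )
    fgt_fraction: float = 0.3
    enhancing_fraction: float = 0.4
    enhancement_amplitude: float = 80.0  # percent
    phase_amplitudes: tuple[float, ...] = (1.0,)  # per post-contrast phase scaling
    tumor_spec: Optional[dict] = None  # {"side": "low"|"high", "center", "radii", "amplitude"}
    noise_sd: float = 0.0
    baseline_signal: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.fgt_fraction, self.enhancing_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.noise_sd < 0 or self.baseline_signal <= 0:
            raise ValueError("noise_sd must be >= 0 and baseline_signal > 0")


@dataclass
class CohortSpec:
    """Size, generative threshold and effect sizes of a simulated cohort."""

    n: int = 300
    generative_threshold: float = 55.0  # k*, percent
    grade_cutpoints: Optional[Sequence[float]] = None  # on BPE(k*); None -> prevalence quantiles
    grade_prevalence: Sequence[float] = DEFAULT_GRADE_PREVALENCE
    misclassification_prob: float = 0.1
    threshold_grid: Sequence[float] = tuple(range(0, 201, 5))
    #: patient-heterogeneity ranges for the enhancement model
    mu_range: tuple[float, float] = (20.0, 120.0)
    sigma_range: tuple[float, float] = (10.0, 60.0)
    fgt_ratio_range: tuple[float, float] = (0.1, 0.6)
    #: covariates
    age_mean: float = 52.0
    age_sd: float = 11.0
    #: outcome effects
    log_hr_os: float = float(np.log(0.58))
    log_hr_rfs: float = float(np.log(0.85))
    os_event_rate: float = 0.35
    rfs_event_rate: float = 0.35
    baseline_hazard: float = 1.0 / 1825.0  # per day
    nac_fraction: float = 0.5
    bpe_shrink_logmean: float = float(np.log(0.55))
    bpe_shrink_logsd: float = 0.45
    log_or_drop: float = float(np.log(6.0))
    log_or_increase: float = 0.0
    pcr_base_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if not 0 <= self.misclassification_prob <= 1:
            raise ValueError("misclassification_prob must be a probability")
        if not 0 < self.os_event_rate < 1 or not 0 < self.rfs_event_rate < 1:
            raise ValueError("event rates must lie in (0, 1)")
        if self.grade_cutpoints is not None:
            c = np.asarray(self.grade_cutpoints, dtype=float)
            if c.shape != (3,) or np.any(np.diff(c) <= 0):
                raise ValueError("grade_cutpoints must be 3 increasing values")


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def _exact_count_trim(n: int, fgt_fraction: float, enhancing_fraction: float) -> int:
    """Largest m <= n for which both designed voxel counts are integral.

    Trimming the breast voxel set to m makes fgt_fraction*m and
    enhancing_fraction*fgt_fraction*m whole numbers, so the designed BPE
    (enhancing_fraction x fgt_fraction) is exact rather than subject to
    rounding.  Falls back to n when no such m exists nearby.
    """
    for m in range(n, max(n - 1000, 0), -1):
        a = fgt_fraction * m
        b = enhancing_fraction * a
        if abs(a - round(a)) < 1e-9 and abs(b - round(b)) < 1e-9:
            return m
    return n


def generate_phantom(spec: PhantomSpec):
    """Build a DCE study, mask set and ground-truth record from a spec.

    Enhancing FGT voxels are chosen by seeded uniform sampling without
    replacement per side, so the designed enhancing fraction is exact by
    construction.  Returns ``(DCEStudy, MaskSet, truth)`` where ``truth``
    records per-side voxel counts and the designed noise-free BPE
    (enhancing_fraction x fgt_fraction) valid at any threshold below the
    enhancement amplitude.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    side_masks = []
    for center, radii in spec.ellipsoids:
        for c, r, s in zip(center, radii, shape):
            if c - r < -0.5 or c + r > s - 0.5:
                raise ValueError("ellipsoid exceeds the grid")
        side_masks.append(_ellipsoid_mask(shape, center, radii))

    fgt = np.zeros(shape, dtype=bool)
    enhancing = np.zeros(shape, dtype=bool)
    breast = np.zeros(shape, dtype=bool)
    truth_sides = []
    for sm in side_masks:
        idx = np.flatnonzero(sm)
        n_breast = _exact_count_trim(len(idx), spec.fgt_fraction, spec.enhancing_fraction)
        idx = rng.choice(idx, size=n_breast, replace=False)
        breast.ravel()[idx] = True
        n_fgt = int(round(spec.fgt_fraction * n_breast))
        fgt_idx = rng.choice(idx, size=n_fgt, replace=False)
        n_enh = int(round(spec.enhancing_fraction * n_fgt))
        enh_idx = rng.choice(fgt_idx, size=n_enh, replace=False)
        fgt.ravel()[fgt_idx] = True
        enhancing.ravel()[enh_idx] = True
        truth_sides.append(
            {"n_breast": n_breast, "n_fgt": n_fgt, "n_enhancing": n_enh,
             "designed_bpe": n_enh / n_breast if n_breast else 0.0}
        )

    tumor = None
    if spec.tumor_spec is not None:
        ts = spec.tumor_spec
        tumor = _ellipsoid_mask(shape, ts["center"], ts["radii"]) & breast

    base = np.full(shape, spec.baseline_signal, dtype=np.float64)
    phases = [base.copy()]
    for amp_scale in spec.phase_amplitudes:
        post = base.copy()
        gain = spec.baseline_signal * (spec.enhancement_amplitude / 100.0) * amp_scale
        post[enhancing] += gain
        if tumor is not None:
            t_gain = spec.baseline_signal * (spec.tumor_spec["amplitude"] / 100.0) * amp_scale
            post[tumor] += t_gain
        phases.append(post)
    if spec.noise_sd > 0:
        phases = [p + rng.normal(0.0, spec.noise_sd, size=shape) for p in phases]

    study = DCEStudy(patient_id="phantom", timepoint="T0", phases=phases,
                     spacing=np.asarray(spec.spacing))
    masks = MaskSet(breast=breast, fgt=fgt, tumor=tumor, spacing=np.asarray(spec.spacing))
    truth = {
        "sides": truth_sides,
        "enhancing_mask": enhancing,
        "fgt_fraction": spec.fgt_fraction,
        "enhancing_fraction": spec.enhancing_fraction,
        "enhancement_amplitude": spec.enhancement_amplitude,
        "designed_bpe": spec.enhancing_fraction * spec.fgt_fraction,
    }
    return study, masks, truth


@dataclass
class SyntheticCohort:
    """A simulated cohort: patient table, analytic threshold sweep, ground truth."""

    cohort: pd.DataFrame
    sweep: pd.DataFrame
    truth: dict


def _bin_grades(values: np.ndarray, cutpoints: np.ndarray) -> np.ndarray:
    return np.searchsorted(cutpoints, values, side="right") + 1


def _flip_grades(grades: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric adjacent-grade flips with probability ``prob`` per patient."""
    out = grades.copy()
    flip = rng.random(len(grades)) < prob
    direction = rng.integers(0, 2, size=len(grades)) * 2 - 1
    out[flip] += direction[flip]
    out[out < 1] = 2  # grade 1 can only flip up, grade 4 only down
    out[out > 4] = 3
    return out


def _administrative_censor_time(hazards: np.ndarray, target_rate: float) -> float:
    """Solve for the follow-up cutoff C with mean P(T <= C) = target event rate."""
    def rate(c):
        return float(np.mean(1.0 - np.exp(-hazards * c))) - target_rate
    hi = 1.0
    while rate(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("infeasible event rate for the given hazards")
    return float(optimize.brentq(rate, 1e-9, hi))


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Simulate a patient cohort with grades derived from BPE at threshold k*.

    Per patient i the FGT enhancement amplitudes are Normal(mu_i, sigma_i)
    and the FGT/breast ratio is r_i, all drawn uniformly from the spec's
    ranges, so the analytic sweep is BPE_i(k) = r_i * Phi-bar((k - mu_i)/sigma_i).
    The radiologist grade bins BPE_i(k*) at the cutpoints (defaults: the
    empirical quantiles matching the reference per-grade prevalences), then
    suffers adjacent-grade flips.  OS/RFS times are exponential with the
    spec's log-HR on the dichotomized grade (high 3/4 vs low 1/2); pCR is
    Bernoulli-logistic on the post-NAC change in predicted grade.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    mu = rng.uniform(*spec.mu_range, size=n)
    sigma = rng.uniform(*spec.sigma_range, size=n)
    ratio = rng.uniform(*spec.fgt_ratio_range, size=n)

    k_star = spec.generative_threshold
    bpe_t0 = ratio * stats.norm.sf(k_star, loc=mu, scale=sigma)
    if spec.grade_cutpoints is None:
        q = np.cumsum(spec.grade_prevalence)[:3]
        cutpoints = np.quantile(bpe_t0, q)
    else:
        cutpoints = np.asarray(spec.grade_cutpoints, dtype=float)
    grade_clean = _bin_grades(bpe_t0, cutpoints)
    radiologist_grade = _flip_grades(grade_clean, spec.misclassification_prob, rng)
    bpe_high = (radiologist_grade >= 3).astype(int)

    # analytic threshold sweep, long format
    grid = np.asarray(spec.threshold_grid, dtype=float)
    sweep_vals = ratio[:, None] * stats.norm.sf(grid[None, :], loc=mu[:, None],
                                                scale=sigma[:, None])
    pids = np.array([f"SYN{i:05d}" for i in range(n)])
    sweep = pd.DataFrame(
        {
            "patient_id": np.repeat(pids, len(grid)),
            "timepoint": "T0",
            "threshold_k": np.tile(grid, n),
            "bpe_value": sweep_vals.ravel(),
        }
    )

    # covariates (independent of outcome by design; only BPE carries effects)
    age = rng.normal(spec.age_mean, spec.age_sd, size=n)
    p_post = 1.0 / (1.0 + np.exp(-(age - 50.0) / 4.0))
    meno = np.where(rng.random(n) < p_post, "post", "pre")
    meno = np.where(rng.random(n) < 0.03, "unknown", meno)
    race = rng.choice(list(RACE_PROBS), size=n, p=np.array(list(RACE_PROBS.values())) /
                      sum(RACE_PROBS.values()))
    subtype = rng.choice(list(SUBTYPE_PROBS), size=n, p=np.array(list(SUBTYPE_PROBS.values())) /
                         sum(SUBTYPE_PROBS.values()))
    hr_status = np.isin(subtype, ["HR+HER2-", "HR+HER2+"]).astype(int)
    her2_status = np.isin(subtype, ["HR+HER2+", "HR-HER2+"]).astype(int)
    tumor_stage = rng.choice([1, 2, 3, 4], size=n, p=[0.3, 0.4, 0.2, 0.1])
    histologic_grade = rng.choice([1, 2, 3], size=n, p=[0.2, 0.45, 0.35])
    node_positive = rng.binomial(1, 0.35, size=n)
    nac = rng.binomial(1, spec.nac_fraction, size=n)

    # survival: exponential PH on the dichotomized grade, administrative censoring
    def survival(log_hr: float, target: float):
        h = spec.baseline_hazard * np.exp(log_hr * bpe_high)
        t_event = rng.exponential(1.0 / h)
        c = _administrative_censor_time(h, target)
        event = (t_event <= c).astype(int)
        return np.minimum(t_event, c), event, c

    os_time, os_event, os_censor = survival(spec.log_hr_os, spec.os_event_rate)
    rfs_time, rfs_event, rfs_censor = survival(spec.log_hr_rfs, spec.rfs_event_rate)

    # post-NAC BPE and pCR
    shrink = np.exp(rng.normal(spec.bpe_shrink_logmean, spec.bpe_shrink_logsd, size=n))
    bpe_t3 = np.where(nac == 1, bpe_t0 * shrink, np.nan)
    grade_t3_clean = np.where(
        nac == 1, _bin_grades(np.nan_to_num(bpe_t3), cutpoints), 0
    )
    drop = ((nac == 1) & (grade_t3_clean < grade_clean)).astype(int)
    increase = ((nac == 1) & (grade_t3_clean > grade_clean)).astype(int)
    logit_base = np.log(spec.pcr_base_rate / (1.0 - spec.pcr_base_rate))
    p_pcr = 1.0 / (1.0 + np.exp(-(logit_base + spec.log_or_drop * drop
                                  + spec.log_or_increase * increase)))
    pcr = np.where(nac == 1, rng.binomial(1, p_pcr), np.nan)

    cohort = pd.DataFrame(
        {
            "patient_id": pids,
            "age_years": age,
            "menopausal_status": meno,
            "race_ethnicity": race,
            "hr_status": hr_status,
            "her2_status": her2_status,
            "molecular_subtype": [derive_subtype(h, e) for h, e in zip(hr_status, her2_status)],
            "tumor_stage": tumor_stage,
            "histologic_grade": histologic_grade,
            "node_positive": node_positive,
            "nac": nac,
            "radiologist_grade": radiologist_grade,
            "bpe_t0": bpe_t0,
            "bpe_t3": bpe_t3,
            "predicted_grade_t0": grade_clean,
            "predicted_grade_t3": np.where(nac == 1, grade_t3_clean, np.nan),
            "os_time": os_time,
            "rfs_time": rfs_time,
            "os_event": os_event,
            "rfs_event": rfs_event,
            "pcr": pcr,
            "bpe_high": bpe_high,
            "drop_in_grade": np.where(nac == 1, drop, np.nan),
            "increase_in_grade": np.where(nac == 1, increase, np.nan),
        }
    )
    truth = {
        "k_star": k_star,
        "cutpoints": cutpoints,
        "log_hr_os": spec.log_hr_os,
        "log_hr_rfs": spec.log_hr_rfs,
        "log_or_drop": spec.log_or_drop,
        "os_censor_time": os_censor,
        "rfs_censor_time": rfs_censor,
        "mu": mu, "sigma": sigma, "fgt_ratio": ratio,
    }
    return SyntheticCohort(cohort=cohort, sweep=sweep, truth=truth)
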