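# Methods

## The quantity being measured

Background parenchymal enhancement (BPE) is the contrast uptake of normal
fibroglandular tissue (FGT) on dynamic contrast-enhanced breast MRI.
Radiologists grade it ordinally (BI-RADS 1–4: minimal, mild, moderate,
marked), with well-documented interobserver variability. The package
quantifies BPE from the images instead. For voxel *j* with pre-contrast
signal S₀ⱼ and *i*-th post-contrast signal Sᵢⱼ, the relative enhancement is

    Eᵢⱼ = (Sᵢⱼ − S₀ⱼ) / S₀ⱼ × 100 %.

The volume-based BPE at enhancement threshold *k* is the volume of refined-FGT
voxels with Eᵢⱼ ≥ *k*%, divided by the breast volume of the analysis side:

    BPE_{i,k} = V(FGT voxels with E ≥ k) / V(Breast).

On a common voxel grid this is a voxel-count ratio. It is dimensionless,
bounded by V_FGT/V_Breast ≤ 1, monotone non-increasing in *k*, and invariant
to any global rescaling of the signal.

### Conventions and numerical choices

- **Positivity floor.** The ratio is undefined at S₀ = 0. Voxels with
  S₀ ≤ 10⁻⁶ (configurable, signal units) are excluded from the FGT numerator
  only; they still count in V_Breast, so the normalizer is untouched.
- **Closed threshold.** The comparison is E ≥ k, so a voxel exactly at the
  threshold counts as enhancing. Negative enhancement is allowed; such voxels
  simply never pass a positive threshold.
- **Per-breast normalization.** V_Breast is the breast volume of the analysis
  side only. BPE is measured on the contralateral (unaffected) breast; the
  single-side normalizer is the convention that makes the contralateral and
  ipsilateral measurements directly comparable.
- **Default phase.** First post-contrast (peak contrast). A delayed-phase
  analysis uses the third post-contrast volume where acquired.
- **Intensity-based variant.** `bpe_intensity` reports the mean relative
  enhancement over valid refined-FGT voxels as a fraction. It is a
  non-canonical summary (unbounded above) kept for comparison only; the
  volume-based statistic drives calibration and outcome models.

## Masks and laterality

Breast, FGT and tumor masks are inputs on the study's grid (segmentation is
out of scope). FGT voxels leaking outside the breast mask are clipped with a
logged count rather than rejected, since segmentation outputs commonly spill
by a few voxels. The refined FGT mask subtracts the tumor (optionally dilated
by a physical margin via a Euclidean distance transform; default margin
0 mm — strict voxel exclusion).

Left/right separation uses the midpoint of the breast mask's bounding box
along a configurable laterality axis (default: first array axis); voxels at
the midpoint go to the lower-index side. A bounding-box rule was chosen over
connected components because FGT can bridge the midline; it is deterministic
and cheap. Contralateral selection picks the side with the smaller tumor
volume (zero beats nonzero; exact ties go to the lower-index side with a
warning; tumor-free studies default to the larger-FGT side so healthy-control
phantoms are analysable). Ipsilateral mode always returns the opposite side.

## Threshold calibration

For each threshold on a grid (default 0–200 % in steps of 5) the Spearman
rank correlation between quantitative BPE and the ordinal radiologist grade
is computed across the cohort; the calibrated threshold is the argmax
(smallest threshold on ties, reported alongside the full curve). Separation
quality is summarized by ROC AUCs of the three cumulative dichotomies
(grade 1 vs 2–4, 1–2 vs 3–4, 1–3 vs 4); AUC equals the concordance
probability with ties counted ½ and is invariant to monotone transforms of
the score, so raw BPE and any logistic transform of it give the same value.

Grade cutpoints on BPE use Youden's J (sensitivity + specificity − 1)
rather than a logistic probability-0.5 crossing: for a single monotone
covariate both criteria order cutpoints identically, and J remains
well-defined under complete separation where a logistic fit diverges.
Candidate cutpoints are midpoints between consecutive distinct BPE values,
so separable cohorts yield cutpoints strictly between the groups and
re-assignment reproduces the grades exactly. The 4-level grading fits the
three cumulative dichotomies independently and repairs any ordering
violation with a running maximum (logged). Assignment is closed on the
right: BPE equal to a cutpoint receives the higher grade.

Longitudinal change across neoadjuvant chemotherapy (NAC; T0 pre-treatment,
T3 post-treatment) is assessed with a paired t test on per-patient BPE
differences, optionally stratified by baseline grade. Two degenerate inputs
are distinguished: all-zero differences return t = 0, p = 1 with a warning
(the natural limit), while zero variance around a nonzero mean raises, since
the statistic is unbounded there.

## Outcome models

The primary predictor is the dichotomized quantitative BPE grade (high 3/4
vs low 1/2) for overall and recurrence-free survival, and the change in
predicted grade across NAC for pathological complete response (pCR).
Survival uses Cox proportional hazards with Efron tie handling; pCR uses
maximum-likelihood logistic regression. Hazard and odds ratios are exp of
the coefficient with Wald 95% intervals on the log scale, so exp of the
coefficient CI equals the reported ratio CI exactly. Candidate covariates
are screened univariately (likelihood-ratio p < 0.05) before entering the
multivariate model; the primary predictor is exempt from screening and
always retained. Stratified analyses (NAC vs primary surgery, menopausal
status, age above/below the cohort median) refit within each stratum,
dropping the stratifying covariate from that stratum's model and re-running
the screen per stratum; strata too small or degenerate are marked
not-estimable rather than aborting the run. Quasi-separated logistic fits
(non-convergence, exploding coefficients) are signalled the same way.
"Unknown" menopausal status is kept as its own category in summaries and
excluded from menopause-stratified models.

## Synthetic data

No raw patient images ship with the package; two generators provide
ground-truth test beds.

**Phantoms** are two-ellipsoid breast volumes. A designed fraction of breast
voxels is FGT and a designed fraction of FGT voxels enhances at a designed
amplitude, both drawn by seeded sampling without replacement, so the
volume-based BPE equals enhancing_fraction × fgt_fraction by construction
for every threshold strictly between zero and the amplitude. Each side's
breast voxel set is trimmed (by at most a few hundred voxels) to the nearest
count that makes both designed products integral, so the recovery is exact
rather than subject to rounding. Noise is additive Gaussian on signal
intensities, applied before the ratio; it can flip voxels near the
threshold, so noisy recovery is checked within a binomial tolerance.
Phantoms do not emulate MRI physics (coil inhomogeneity, motion, fat
suppression) — passing tests show the estimator is correct on its inputs,
not that segmentation or acquisition artifacts are handled.

**Cohorts** emulate the statistical structure the analysis assumes. Patient
*i* carries a Gaussian FGT enhancement-amplitude distribution (mean μᵢ ~
U(20, 120) %, spread σᵢ ~ U(10, 60) %) and an FGT/breast volume ratio rᵢ ~
U(0.1, 0.6), giving the analytic threshold sweep BPEᵢ(k) = rᵢ · P(amplitude
≥ k). The radiologist grade bins BPE at the generative threshold k* (default
55 %) at cutpoints matching the reference per-grade prevalences
(44/28/19/9 %), then suffers symmetric adjacent-grade flips with probability
0.1, emulating interobserver variability. The heterogeneity in (μ, σ, r) is
what makes k* identifiable: the cohort ranking by BPE(k) drifts with k, so
the rank correlation with the grade peaks at the generative threshold.
Because grading is nearly deterministic given BPE(k*), the synthetic
dichotomy AUCs are higher than those seen on clinical data; the recovery
tests validate the calibration machinery, not the clinical effect size.

Survival times are exponential with the specified log-HR (default ln 0.58
for OS) applied to the observed dichotomized grade; administrative censoring
at a follow-up cutoff solved numerically (Brent) for a 35 % event rate.
pCR is Bernoulli-logistic on the post-NAC change in predicted grade
(default log-OR ln 6 for a grade drop, base rate 0.2); post-NAC BPE is the
baseline value times a log-normal shrink factor (median ≈ 0.55), which
mostly lowers and occasionally raises the grade. All sampling flows from a
single `numpy` PCG64 generator, so a fixed seed reproduces every volume and
table bit-for-bit.

## Problem sizes used in the shipped checks

Oracle equivalence uses ≥100 random grids up to 8×8×8 (exact equality with
a per-voxel loop). Threshold recovery uses 20 seeds × 3 generative
thresholds at n = 300. Survival recovery uses 200 seeds at n = 900 with a
35 % event rate; pCR recovery 200 strata of n = 60; screening calibration
500 null replicates at n = 300. These sizes put Monte-Carlo error well below
the asserted tolerances while keeping the default suite fast.

## Known limitations

- Masks are trusted inputs; no segmentation, registration across
  timepoints, or resampling to a common resolution is performed (studies are
  analysed on their native grids).
- The intensity-based BPE variant is a stand-in mean-enhancement summary,
  not a validated alternative definition.
- The cohort generator draws covariates independently of outcomes (only the
  BPE terms carry effects), so it cannot probe confounding structure.
- Proportional hazards and exponential baselines are assumed in generation
  and fitting alike; the generators cannot detect PH violations in real data.
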