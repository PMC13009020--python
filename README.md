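# bpemri

Automated quantification of background parenchymal enhancement (BPE) from
breast DCE-MRI, with threshold calibration against radiologist grades and
downstream outcome modelling. Intended for radiology and imaging-biomarker
researchers who have co-registered DCE phase volumes and breast / FGT /
tumor masks and want an objective, reproducible alternative to visual
BI-RADS BPE grading.

## What it computes

For voxel *j* with pre-contrast signal S₀ⱼ and post-contrast signal Sᵢⱼ,
the relative enhancement is Eᵢⱼ = (Sᵢⱼ − S₀ⱼ)/S₀ⱼ × 100 %. The volume-based
BPE at enhancement threshold *k* is

    BPE_{i,k} = V(FGT voxels with E_ij ≥ k%) / V(Breast),

measured on the contralateral (unaffected) breast with tumor voxels removed
from the FGT mask. The pipeline then

- sweeps *k* over a grid and calibrates it by maximizing the Spearman rank
  correlation with ordinal radiologist grades (1–4), reporting ROC AUCs for
  the grade dichotomies 1 vs 2–4, 1–2 vs 3–4 and 1–3 vs 4;
- fits monotone BPE cutpoints (Youden's J) that map the quantitative value
  back to a predicted grade, 2-level (1/2 vs 3/4) and 4-level;
- tests longitudinal BPE change across neoadjuvant chemotherapy (paired t);
- feeds the dichotomized grade into Cox models for overall and
  recurrence-free survival, and the post-NAC grade change into logistic
  models for pathological complete response, with univariate covariate
  screening and stratified refits.

A synthetic module generates DCE phantoms with exactly known BPE and
simulated cohorts whose grades derive from BPE at a known generative
threshold, so every stage is testable without patient data. See
`docs/methods.md` for model details and assumptions.

## Worked example

```python
from bpemri import *
from bpemri.synthetic_data import PhantomSpec, CohortSpec, generate_phantom, generate_cohort
from bpemri.mask_ops import split_laterality, select_analysis_side, refine_fgt

# a noise-free phantom: 50% of breast is FGT, 40% of FGT enhances at 80%
spec = PhantomSpec(fgt_fraction=0.5, enhancing_fraction=0.4,
                   enhancement_amplitude=80.0, noise_sd=0.0, seed=7)
study, masks, truth = generate_phantom(spec)
masks.refined_fgt = refine_fgt(masks)
lat = select_analysis_side(split_laterality(masks, axis=0), mode="contralateral")
enh = enhancement_map(study, phase_index=1)
m = bpe_volume(enh, lat.analysis_refined_fgt, lat.analysis_breast,
               threshold_k=55.0, voxel_vol=voxel_volume(study))
print(f"BPE at k=55%: {m.value:.4f} (designed {truth['designed_bpe']:.2f})")

# a simulated cohort whose grades derive from BPE at k* = 55%
syn = generate_cohort(CohortSpec(n=300, generative_threshold=55.0, seed=1))
curve = optimize_threshold(syn.sweep, syn.cohort)
opt = curve.at_optimum()
print(f"optimal threshold: {curve.optimal_k:.0f}% (rho={opt['rho']:.3f})")
est = fit_cox(syn.cohort, "OS", "bpe_high", ["age_years"])
print(f"OS adjusted HR (high vs low BPE): {est.point:.2f} "
      f"[{est.ci_low:.2f}, {est.ci_high:.2f}], p={est.p_value:.3f}")
```

prints

```
BPE at k=55%: 0.2000 (designed 0.20)
optimal threshold: 50% (rho=0.913)
OS adjusted HR (high vs low BPE): 0.67 [0.43, 1.06], p=0.090
```

The phantom's BPE is recovered exactly (0.4 × 0.5 = 0.20). On this seed the
calibrated threshold lands one grid step from the generative 55 % — the
rank-correlation curve is flat near its peak, so single-cohort recovery is
accurate to about one step. The hazard ratio below 1 reflects the cohort's
built-in protective association between high BPE and overall survival.

## Command line

```sh
bpe simulate phantom --out out/ph --seed 1        # NIfTI volumes + manifest
bpe quantify --manifest out/ph/manifest.csv --out sweep.csv \
    --thresholds 0:200:5 --side contralateral
bpe simulate cohort --out out/coh --seed 1        # cohort.csv + sweep.csv
bpe run-all --config config.yaml --out out/run    # quantify→calibrate→grade→outcomes
```

Every run writes its resolved config and intermediate CSV/JSON, and is
byte-reproducible for a fixed config and seed.

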