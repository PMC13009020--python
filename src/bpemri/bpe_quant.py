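"""Quantitative BPE: relative enhancement maps and the volume-based statistic.

For voxel j with pre-contrast signal S0_j and post-contrast signal Si_j, the
relative enhancement is

    E_ij = (Si_j - S0_j) / S0_j * 100  [percent].

The volume-based BPE at enhancement threshold k is the volume of refined-FGT
voxels with E_ij >= k%, divided by the breast volume of the analysis side:

    BPE_{i,k} = V(FGT voxels with E >= k) / V(Breast).

Because every voxel carries the same volume on a common grid, this reduces to
a voxel-count ratio.  BPE is dimensionless, lies in [0, V_FGT/V_Breast] and is
invariant to any global rescaling of the signal.

An intensity-based variant (the mean relative enhancement over refined-FGT
voxels) is also provided.  It is a non-canonical stand-in summary statistic,
kept separate from the volume-based method used for calibration and outcomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from bpemri.imaging_io import DCEStudy
from bpemri.mask_ops import LateralizedMasks

logger = logging.getLogger(__name__)

#: pre-contrast signal floor below which the enhancement ratio is undefined
DEFAULT_POSITIVITY_FLOOR = 1e-6

#: default threshold grid, percent
DEFAULT_THRESHOLDS = tuple(range(0, 201, 5))


@dataclass
class EnhancementMap:
    """Per-voxel relative enhancement (percent) with a validity mask.

    ``valid`` marks voxels whose pre-contrast signal exceeds the positivity
    floor; enhancement is undefined (and excluded downstream) elsewhere.
    """

    values: np.ndarray
    valid: np.ndarray
    phase_index: int

    def __post_init__(self) -> None:
        if self.phase_index < 1:
            raise ValueError("phase_index must address a post-contrast phase (>= 1)")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("enhancement must be finite wherever valid")


@dataclass
class BPEMeasurement:
    """One scalar BPE value with its provenance."""

    value: float
    method: str  # "volume" | "intensity"
    phase_index: int
    threshold_k: Optional[float] = None  # percent; volume method only
    side: Optional[str] = None
    fgt_voxels_used: int = 0
    v_breast_mm3: float = np.nan
    v_fgt_mm3: float = np.nan

    def __post_init__(self) -> None:
        if self.method == "volume":
            if self.threshold_k is None:
                raise ValueError("volume method requires threshold_k")
            if not (0.0 <= self.value <= 1.0 + 1e-12):
                raise ValueError(f"volume-based BPE out of [0,1]: {self.value}")
        elif self.method == "intensity":
            if self.threshold_k is not None:
                raise ValueError("intensity method takes no threshold")
        else:
            raise ValueError(f"unknown method {self.method!r}")


def enhancement_map(
    study: DCEStudy,
    phase_index: int = 1,
    positivity_floor: float = DEFAULT_POSITIVITY_FLOOR,
) -> EnhancementMap:
    """Relative enhancement of post-contrast phase ``phase_index`` vs pre-contrast.

    Voxels whose pre-contrast signal is at or below ``positivity_floor`` are
    marked invalid (the ratio is undefined at S0 = 0); they still count toward
    breast volume downstream.  Negative enhancement is allowed — darker voxels
    simply never pass a positive threshold.
    """
    if not 1 <= phase_index < study.n_phases:
        raise IndexError(
            f"phase_index {phase_index} out of range [1, {study.n_phases - 1}]"
        )
    s0 = study.phases[0]
    si = study.phases[phase_index]
    valid = s0 > positivity_floor
    values = np.zeros_like(s0)
    np.divide(si - s0, s0, out=values, where=valid)
    values *= 100.0
    n_invalid = int(valid.size - np.count_nonzero(valid))
    if n_invalid:
        logger.debug("enhancement undefined at %d voxels (S0 <= floor)", n_invalid)
    return EnhancementMap(values=values, valid=valid, phase_index=phase_index)


def bpe_volume(
    enh: EnhancementMap,
    refined_fgt: np.ndarray,
    breast: np.ndarray,
    threshold_k: float,
    voxel_vol: float = 1.0,
    side: Optional[str] = None,
) -> BPEMeasurement:
    """Volume-based BPE at enhancement threshold ``threshold_k`` (percent).

    Numerator: refined-FGT voxels that are valid and enhance by >= k%
    (closed comparison).  Denominator: all breast voxels of the analysis side,
    including invalid ones — validity filtering narrows the FGT set only, so
    the breast-volume normalizer is untouched.
    """
    breast = np.asarray(breast, dtype=bool)
    refined_fgt = np.asarray(refined_fgt, dtype=bool)
    if breast.shape != enh.values.shape or refined_fgt.shape != enh.values.shape:
        raise ValueError("masks must share the enhancement map's grid")
    n_breast = int(np.count_nonzero(breast))
    if n_breast == 0:
        raise ValueError("breast mask is empty")
    usable = refined_fgt & enh.valid
    n_fgt = int(np.count_nonzero(usable))
    if n_fgt == 0:
        logger.warning("no valid refined-FGT voxels; BPE = 0")
    n_enh = int(np.count_nonzero(usable & (enh.values >= threshold_k)))
    return BPEMeasurement(
        value=n_enh / n_breast,
        method="volume",
        phase_index=enh.phase_index,
        threshold_k=float(threshold_k),
        side=side,
        fgt_voxels_used=n_fgt,
        v_breast_mm3=n_breast * voxel_vol,
        v_fgt_mm3=int(np.count_nonzero(refined_fgt)) * voxel_vol,
    )


def bpe_intensity(
    enh: EnhancementMap,
    refined_fgt: np.ndarray,
    voxel_vol: float = 1.0,
    side: Optional[str] = None,
) -> BPEMeasurement:
    """Intensity-based BPE: mean relative enhancement over valid refined-FGT voxels.

    Reported as a fraction (percent / 100); unlike the volume-based statistic
    it is unbounded above and may exceed 1.  Non-canonical summary variant.
    """
    refined_fgt = np.asarray(refined_fgt, dtype=bool)
    usable = refined_fgt & enh.valid
    n_fgt = int(np.count_nonzero(usable))
    if n_fgt == 0:
        raise ValueError("no valid refined-FGT voxels for intensity-based BPE")
    mean_pct = float(np.mean(enh.values[usable]))
    return BPEMeasurement(
        value=mean_pct / 100.0,
        method="intensity",
        phase_index=enh.phase_index,
        side=side,
        fgt_voxels_used=n_fgt,
        v_fgt_mm3=int(np.count_nonzero(refined_fgt)) * voxel_vol,
    )


def bpe_sweep(
    study: DCEStudy,
    lat: LateralizedMasks,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    phase_indices: Sequence[int] = (1,),
    positivity_floor: float = DEFAULT_POSITIVITY_FLOOR,
) -> pd.DataFrame:
    """BPE over a threshold grid and one or more post-contrast phases.

    Returns a long-format table with one row per (phase_index, threshold_k),
    non-increasing in threshold for each phase.  The analysis side must
    already be selected on ``lat``.
    """
    if lat.analysis_side is None:
        raise ValueError("analysis side not selected; call select_analysis_side first")
    if len(thresholds) == 0:
        raise ValueError("threshold grid is empty")
    voxel_vol = float(np.prod(study.spacing))
    breast = lat.analysis_breast
    fgt = lat.analysis_refined_fgt
    rows = []
    for pi in phase_indices:
        enh = enhancement_map(study, pi, positivity_floor)
        usable = fgt & enh.valid
        vals = np.sort(enh.values[usable])
        n_breast = int(np.count_nonzero(breast))
        if n_breast == 0:
            raise ValueError("breast mask empty on the analysis side")
        # counts of vals >= k via one sorted pass instead of a scan per threshold
        for k in thresholds:
            n_enh = len(vals) - int(np.searchsorted(vals, k, side="left"))
            rows.append(
                {
                    "patient_id": study.patient_id,
                    "timepoint": study.timepoint,
                    "side": lat.analysis_side,
                    "method": "volume",
                    "phase_index": pi,
                    "threshold_k": float(k),
                    "bpe_value": n_enh / n_breast,
                    "v_breast_mm3": n_breast * voxel_vol,
                    "v_fgt_mm3": int(np.count_nonzero(fgt)) * voxel_vol,
                    "fgt_voxels_used": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)
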