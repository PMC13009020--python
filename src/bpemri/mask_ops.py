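"""Laterality splitting, analysis-side selection and FGT refinement.

BPE is measured on the contralateral (unaffected) breast to avoid tumor
confounding; with bilateral disease the side with the smaller tumor volume is
treated as contralateral.  Tumor voxels are always subtracted from the FGT
mask before any enhancement statistics are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from bpemri.imaging_io import MaskSet

logger = logging.getLogger(__name__)

CONTRALATERAL = "contralateral"
IPSILATERAL = "ipsilateral"


@dataclass
class LateralizedMasks:
    """Breast/FGT masks split into two sides along the laterality axis.

    ``side_low`` / ``side_high`` are boolean side-assignment volumes for the
    lower- and higher-coordinate halves; they partition the breast mask.
    ``analysis_side`` is set by :func:`select_analysis_side`.
    """

    masks: MaskSet
    axis: int
    side_low: np.ndarray
    side_high: np.ndarray
    analysis_side: Optional[str] = None  # "low" | "high"
    selection_mode: Optional[str] = None

    def side_mask(self, which: str) -> np.ndarray:
        return self.side_low if which == "low" else self.side_high

    @property
    def analysis_breast(self) -> np.ndarray:
        return self.masks.breast & self.side_mask(self.analysis_side)

    @property
    def analysis_refined_fgt(self) -> np.ndarray:
        fgt = self.masks.refined_fgt if self.masks.refined_fgt is not None else self.masks.fgt
        return fgt & self.side_mask(self.analysis_side)


def split_laterality(masks: MaskSet, axis: int = 0) -> LateralizedMasks:
    """Assign every breast voxel to one side of the midline.

    The midline is the midpoint of the breast mask's bounding box along
    ``axis``; voxels at or below the midpoint go to the lower-index side.
    This is deterministic and robust to FGT bridging across the midline,
    unlike a connected-component split.
    """
    breast = masks.breast
    if not breast.any():
        raise ValueError("breast mask is empty")
    coords = np.nonzero(breast.any(axis=tuple(i for i in range(3) if i != axis)))[0]
    lo, hi = int(coords.min()), int(coords.max())
    midpoint = (lo + hi) / 2.0
    idx = np.arange(breast.shape[axis])
    low_sel = idx <= midpoint
    shape = [1, 1, 1]
    shape[axis] = breast.shape[axis]
    low_vol = np.broadcast_to(low_sel.reshape(shape), breast.shape)
    side_low = np.ascontiguousarray(low_vol)
    side_high = ~side_low
    return LateralizedMasks(masks=masks, axis=axis, side_low=side_low, side_high=side_high)


def select_analysis_side(
    lat: LateralizedMasks,
    tumor: Optional[np.ndarray] = None,
    mode: str = CONTRALATERAL,
) -> LateralizedMasks:
    """Pick the analysis side given the tumor mask.

    Contralateral mode selects the side with the smaller tumor volume (zero
    beats nonzero); an exact tie goes to the lower-index side with a warning.
    With no tumor at all (healthy-control phantoms) the larger-FGT side is
    used.  Ipsilateral mode returns the opposite side of whatever
    contralateral mode would pick, so the two modes are always complementary.
    """
    if mode not in (CONTRALATERAL, IPSILATERAL):
        raise ValueError(f"mode must be contralateral or ipsilateral, got {mode!r}")
    if tumor is None:
        tumor = lat.masks.tumor
    if tumor is None or not tumor.any():
        fgt = lat.masks.fgt
        n_low = int(np.count_nonzero(fgt & lat.side_low))
        n_high = int(np.count_nonzero(fgt & lat.side_high))
        contra = "low" if n_low >= n_high else "high"
        logger.info("no tumor voxels; contralateral defaults to larger-FGT side (%s)", contra)
    else:
        t_low = int(np.count_nonzero(tumor & lat.side_low))
        t_high = int(np.count_nonzero(tumor & lat.side_high))
        if t_low == t_high:
            logger.warning("equal tumor volume on both sides; choosing lower-index side")
            contra = "low"
        else:
            contra = "low" if t_low < t_high else "high"
    chosen = contra if mode == CONTRALATERAL else ("high" if contra == "low" else "low")
    return LateralizedMasks(
        masks=lat.masks,
        axis=lat.axis,
        side_low=lat.side_low,
        side_high=lat.side_high,
        analysis_side=chosen,
        selection_mode=mode,
    )


def refine_fgt(masks: MaskSet, margin_mm: float = 0.0) -> np.ndarray:
    """Subtract the (optionally dilated) tumor mask from the FGT mask.

    ``margin_mm`` dilates the tumor by a physical distance before subtraction
    (default 0: strict voxelwise exclusion of tumor voxels).  An empty result
    is legal and logged.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be non-negative")
    fgt = masks.fgt
    tumor = masks.tumor
    if tumor is None or not tumor.any():
        return fgt.copy()
    if margin_mm > 0:
        dist = ndimage.distance_transform_edt(~tumor, sampling=masks.spacing)
        excl = dist <= margin_mm
    else:
        excl = tumor
    refined = fgt & ~excl
    if not refined.any():
        logger.warning("refined FGT mask is empty after tumor exclusion")
    return refined
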