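"""Reading and validation of DCE-MRI volumes and binary masks.

A DCE study is an ordered stack of co-registered 3-D volumes: one pre-contrast
phase (index 0) followed by one or more post-contrast phases acquired after
gadolinium injection.  Breast / FGT / tumor masks live on the same voxel grid.
Volumes are used in stored voxel order; no reorientation to anatomical axes is
attempted (the laterality axis is configurable downstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: spacing agreement tolerance across phases/masks, mm (header rounding slack)
SPACING_TOL_MM = 1e-3


class GridMismatchError(ValueError):
    """Raised when a volume or mask disagrees with the reference voxel grid."""


@dataclass
class DCEStudy:
    """One patient-timepoint: ordered DCE phases on a common grid.

    ``phases[0]`` is the pre-contrast volume (S0); ``phases[i]`` for i >= 1 are
    post-contrast volumes (Si).  ``spacing`` is mm per voxel along each array
    axis.
    """

    patient_id: str
    timepoint: str  # "T0" (pre-treatment) or "T3" (post-NAC)
    phases: list[np.ndarray]
    spacing: np.ndarray

    def __post_init__(self) -> None:
        if len(self.phases) < 2:
            raise ValueError("a DCE study needs a pre-contrast and >=1 post-contrast phase")
        self.phases = [np.asarray(p, dtype=np.float64) for p in self.phases]
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be 3 positive components, got {self.spacing}")
        shape0 = self.phases[0].shape
        if len(shape0) != 3:
            raise ValueError(f"phases must be 3-D, got shape {shape0}")
        for i, p in enumerate(self.phases[1:], start=1):
            if p.shape != shape0:
                raise GridMismatchError(
                    f"phase {i} shape {p.shape} != phase 0 shape {shape0}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.phases[0].shape

    @property
    def n_phases(self) -> int:
        return len(self.phases)


@dataclass
class MaskSet:
    """Co-registered binary masks: breast, FGT, optional tumor, derived refined FGT.

    Invariants enforced at construction: fgt is a subset of breast (leaking
    voxels are clipped with a logged count, since segmentation outputs commonly
    spill by a few voxels); refined_fgt, when present, is a subset of fgt and
    disjoint from tumor.
    """

    breast: np.ndarray
    fgt: np.ndarray
    tumor: Optional[np.ndarray] = None
    refined_fgt: Optional[np.ndarray] = None
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.breast = np.asarray(self.breast, dtype=bool)
        self.fgt = np.asarray(self.fgt, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        if self.fgt.shape != self.breast.shape:
            raise GridMismatchError("fgt and breast masks differ in shape")
        leaked = int(np.count_nonzero(self.fgt & ~self.breast))
        if leaked:
            logger.warning("clipped %d FGT voxels outside the breast mask", leaked)
            self.fgt = self.fgt & self.breast
        if self.tumor is not None:
            self.tumor = np.asarray(self.tumor, dtype=bool)
            if self.tumor.shape != self.breast.shape:
                raise GridMismatchError("tumor mask differs in shape from breast mask")
        if self.refined_fgt is not None:
            self.refined_fgt = np.asarray(self.refined_fgt, dtype=bool)
            if self.refined_fgt.shape != self.breast.shape:
                raise GridMismatchError("refined_fgt mask differs in shape")
            if np.any(self.refined_fgt & ~self.fgt):
                raise ValueError("refined_fgt must be a subset of fgt")
            if self.tumor is not None and np.any(self.refined_fgt & self.tumor):
                raise ValueError("refined_fgt must be disjoint from tumor")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.breast.shape


def _load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; return (data, spacing in mm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=np.float64)
    return data, spacing


def save_volume(data: np.ndarray, spacing: Sequence[float], path: str | Path) -> None:
    """Write a volume as NIfTI with a diagonal affine built from the spacing."""
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


def load_dce_study(
    volume_refs: Sequence[str | Path],
    timepoint: str = "T0",
    patient_id: str = "unknown",
) -> DCEStudy:
    """Load an ordered list of phase volumes into a :class:`DCEStudy`.

    The first reference is the pre-contrast phase.  Grid metadata is taken from
    the first volume's header; later volumes must match its shape exactly and
    its spacing to within ``SPACING_TOL_MM``.
    """
    if len(volume_refs) < 2:
        raise ValueError("need >= 2 phase volumes (pre-contrast + post-contrast)")
    phases: list[np.ndarray] = []
    spacing: np.ndarray | None = None
    for i, ref in enumerate(volume_refs):
        data, sp = _load_volume(ref)
        if spacing is None:
            spacing = sp
        else:
            if data.shape != phases[0].shape:
                raise GridMismatchError(
                    f"phase {i} shape {data.shape} != phase 0 shape {phases[0].shape}"
                )
            if np.any(np.abs(sp - spacing) > SPACING_TOL_MM):
                raise GridMismatchError(
                    f"phase {i} spacing {sp} deviates from phase 0 spacing {spacing}"
                )
        phases.append(data)
    return DCEStudy(patient_id=patient_id, timepoint=timepoint, phases=phases, spacing=spacing)


def load_mask(mask_ref: str | Path, reference: DCEStudy) -> np.ndarray:
    """Load a binary mask on the reference study's grid.

    Values other than {0, 1} are coerced: any value > 0 becomes 1 (a warning
    logs the count).  Non-finite voxels or a grid mismatch raise.
    """
    data, sp = _load_volume(mask_ref)
    if data.shape != reference.shape:
        raise GridMismatchError(
            f"mask shape {data.shape} != study shape {reference.shape}"
        )
    if np.any(np.abs(sp - reference.spacing) > SPACING_TOL_MM):
        raise GridMismatchError(
            f"mask spacing {sp} deviates from study spacing {reference.spacing}"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{mask_ref}: mask contains non-finite voxels")
    nonbinary = int(np.count_nonzero((data != 0) & (data != 1)))
    if nonbinary:
        logger.warning("%s: coerced %d non-binary voxels to {0,1}", mask_ref, nonbinary)
    return data > 0


def voxel_volume(study: DCEStudy) -> float:
    """Volume of one voxel in mm^3 (product of the spacing components)."""
    return float(np.prod(study.spacing))


def load_manifest(manifest_csv: str | Path):
    """Read a per-patient manifest CSV into (studies, mask arrays).

    Expected columns: patient_id, timepoint, phase_index, path, mask_role.
    Rows with empty ``mask_role`` are phase volumes ordered by ``phase_index``;
    rows with mask_role in {breast, fgt, tumor} are masks.

    Returns a dict keyed by (patient_id, timepoint) with values
    ``{"study": DCEStudy, "masks": MaskSet}``.
    """
    df = pd.read_csv(manifest_csv, dtype={"patient_id": str})
    if "mask_role" not in df.columns:
        df["mask_role"] = ""
    df["mask_role"] = df["mask_role"].fillna("")
    out = {}
    base = Path(manifest_csv).parent
    for (pid, tp), grp in df.groupby(["patient_id", "timepoint"], sort=True):
        phase_rows = grp[grp["mask_role"] == ""].sort_values("phase_index")
        paths = [
            p if Path(p).is_absolute() else base / p for p in phase_rows["path"]
        ]
        study = load_dce_study(paths, timepoint=str(tp), patient_id=str(pid))
        masks = {}
        for _, row in grp[grp["mask_role"] != ""].iterrows():
            p = Path(row["path"])
            masks[row["mask_role"]] = load_mask(p if p.is_absolute() else base / p, study)
        if "breast" not in masks or "fgt" not in masks:
            raise ValueError(f"manifest entry ({pid}, {tp}) lacks breast or fgt mask")
        mask_set = MaskSet(
            breast=masks["breast"],
            fgt=masks["fgt"],
            tumor=masks.get("tumor"),
            spacing=study.spacing,
        )
        out[(str(pid), str(tp))] = {"study": study, "masks": mask_set}
    return out
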