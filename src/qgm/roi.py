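"""Region-of-interest construction and weighted parameter extraction.

ROIs follow the study design for gray-matter quantitative MRI:

* **cortex** — the GM PVE map restricted to voxels with PVE >= 0.95,
  minus non-cortical structures (deep GM, hole-filled WM, ventricles,
  optional cerebellum), minus lesions, and gated to an absolute-T1
  window of [1200, 1600] ms to remove artifacts and residual
  non-cortical tissue; the surviving PVE values act as weights.
* **deep GM** (thalamus, caudate, putamen, pallidum) — binary masks,
  hemispheres combined, eroded with a 3x3x3 mm^3 cube to avoid CSF
  partial voluming, lesions removed.
* **NAWM** — WM PVE binarized at 0.95, eroded with a 6x6x6 mm^3 cube,
  lesions removed.
* **whole brain** — parameter-specific CSF exclusion: T1 <= 1600 ms for
  the T1 analysis and PD <= 84.44 pu (the Fatouros equivalent of that
  T1 cutoff) for the PD analysis.
* **global GM** — voxelwise maximum of the cortex weights and binary
  deep-GM membership.

Per-ROI parameter values are weight-averaged: sum(w v) / sum(w) over
voxels that pass the fit-validity mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from qgm.phantom import DEEP_GM
from qgm.relaxometry import FatourosCalibration, QuantitativeMapSet, csf_pd_threshold

__all__ = [
    "RoiSet",
    "RoiMeasurement",
    "RoiThresholds",
    "build_cortex_pve",
    "erode_mask",
    "build_deep_gm_rois",
    "build_nawm_roi",
    "build_whole_brain_masks",
    "build_global_gm",
    "weighted_roi_mean",
    "extract_rois",
    "measure_subject",
    "measurements_table",
]

ROI_NAMES = ("nagm", "cortex") + DEEP_GM + ("nawm", "whole_brain")


@dataclass(frozen=True)
class RoiThresholds:
    """All printed constants of the ROI stage, overridable in config."""

    cortex_pve_min: float = 0.95
    cortex_t1_window: tuple[float, float] = (1200.0, 1600.0)  # ms
    wm_pve_min: float = 0.95
    whole_brain_t1_max: float = 1600.0  # ms
    deep_gm_kernel_mm: float = 3.0
    wm_kernel_mm: float = 6.0
    whole_brain_joint_mask: bool = False  # True: conjunctive T1+PD exclusion


@dataclass
class RoiSet:
    """Named ROI weight maps; binary except the cortex contribution."""

    cortex: np.ndarray  # PVE weights in [0, 1]
    thalamus: np.ndarray
    caudate: np.ndarray
    putamen: np.ndarray
    pallidum: np.ndarray
    nawm: np.ndarray
    whole_brain_t1: np.ndarray
    whole_brain_pd: np.ndarray
    global_gm: np.ndarray
    voxel_size: float
    empty_rois: tuple[str, ...] = ()

    def weights(self, roi: str, parameter: str) -> np.ndarray:
        if roi == "whole_brain":
            return self.whole_brain_t1 if parameter == "t1" else self.whole_brain_pd
        if roi == "nagm":
            return self.global_gm
        return getattr(self, roi)


@dataclass
class RoiMeasurement:
    subject_id: str
    roi: str
    parameter: str  # 't1' | 'pd'
    mean: float  # weighted mean; NaN when the ROI is empty
    weight_sum: float
    n_voxels: int

    @property
    def empty(self) -> bool:
        return self.weight_sum <= 0


def erode_mask(mask: np.ndarray, kernel_mm: float, voxel_size: float | tuple[float, ...]) -> np.ndarray:
    """Binary erosion with a cubic kernel specified in millimetres.

    The kernel edge in voxels is round(kernel_mm / voxel_size) per axis,
    forced odd (decremented by one if even, minimum 1); an edge of 1 is
    the identity.  Anisotropic voxel sizes get per-axis edges.
    """
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * mask.ndim
    edges = []
    for vs in voxel_size:
        if kernel_mm < vs:
            edges.append(1)
            continue
        e = int(round(kernel_mm / vs))
        if e % 2 == 0:
            e -= 1
        edges.append(max(e, 1))
    if all(e == 1 for e in edges):
        return mask.astype(bool).copy()
    structure = np.ones(tuple(edges), dtype=bool)
    return ndimage.binary_erosion(mask.astype(bool), structure=structure)


def build_cortex_pve(
    gm_pve: np.ndarray,
    t1: np.ndarray,
    exclusion_mask: np.ndarray,
    lesion_mask: np.ndarray,
    thresholds: RoiThresholds | None = None,
) -> np.ndarray:
    """Cortical PVE weight map after all exclusions and the T1 gate."""
    if thresholds is None:
        thresholds = RoiThresholds()
    lo, hi = thresholds.cortex_t1_window
    keep = (
        (gm_pve >= thresholds.cortex_pve_min)
        & ~exclusion_mask.astype(bool)
        & ~lesion_mask.astype(bool)
        & (t1 >= lo)
        & (t1 <= hi)
    )
    return np.where(keep, gm_pve, 0.0)


def cortex_exclusion_mask(
    deep_gm_masks: dict[str, np.ndarray],
    wm_mask: np.ndarray,
    ventricle_mask: np.ndarray,
    cerebellum_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Union of non-cortical structures; the WM part is hole-filled so
    lesions embedded in WM cannot leak into the cortical map."""
    wm_filled = ndimage.binary_fill_holes(wm_mask.astype(bool))
    excl = wm_filled | ventricle_mask.astype(bool)
    for m in deep_gm_masks.values():
        excl |= m.astype(bool)
    if cerebellum_mask is not None:
        excl |= cerebellum_mask.astype(bool)
    return excl


def build_deep_gm_rois(
    structure_masks: dict[str, np.ndarray],
    voxel_size: float,
    lesion_mask: np.ndarray,
    thresholds: RoiThresholds | None = None,
) -> dict[str, np.ndarray]:
    """Erode each deep-GM structure with the 3 mm cube, drop lesion voxels."""
    if thresholds is None:
        thresholds = RoiThresholds()
    out = {}
    for name in DEEP_GM:
        eroded = erode_mask(structure_masks[name], thresholds.deep_gm_kernel_mm, voxel_size)
        out[name] = eroded & ~lesion_mask.astype(bool)
    return out


def build_nawm_roi(
    wm_pve: np.ndarray,
    lesion_mask: np.ndarray,
    voxel_size: float,
    thresholds: RoiThresholds | None = None,
    exclusion_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Normal-appearing WM: binarized WM PVE, 6 mm erosion, lesions removed.

    ``exclusion_mask`` optionally removes known non-WM structures that an
    intensity-only segmentation tends to misclassify as WM (the iron-rich
    pallidum is nearly isointense with WM on a T1-weighted anatomy).
    """
    if thresholds is None:
        thresholds = RoiThresholds()
    wm = wm_pve >= thresholds.wm_pve_min
    if exclusion_mask is not None:
        wm = wm & ~exclusion_mask.astype(bool)
    return erode_mask(wm, thresholds.wm_kernel_mm, voxel_size) & ~lesion_mask.astype(bool)


def build_whole_brain_masks(
    t1: np.ndarray,
    pd: np.ndarray,
    brain_mask: np.ndarray,
    cal: FatourosCalibration | None = None,
    lesion_mask: np.ndarray | None = None,
    thresholds: RoiThresholds | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Whole-brain masks with CSF excluded by parameter-specific cutoffs.

    Returns (t1_mask, pd_mask).  The PD cutoff is the water content the
    Fatouros relation assigns to the T1 cutoff (84.44 pu at 1600 ms for
    the default calibration).  With ``whole_brain_joint_mask`` both
    cutoffs apply to both masks (conjunctive alternative).
    """
    if thresholds is None:
        thresholds = RoiThresholds()
    pd_max = csf_pd_threshold(cal, thresholds.whole_brain_t1_max)
    base = brain_mask.astype(bool)
    if lesion_mask is not None:
        base = base & ~lesion_mask.astype(bool)
    t1_mask = base & (t1 <= thresholds.whole_brain_t1_max)
    pd_mask = base & (pd <= pd_max)
    if thresholds.whole_brain_joint_mask:
        joint = t1_mask & pd_mask
        return joint, joint.copy()
    return t1_mask, pd_mask


def build_global_gm(
    cortex_weights: np.ndarray, deep_gm_rois: dict[str, np.ndarray]
) -> np.ndarray:
    """Global GM weights: max of cortex PVE and binary deep-GM membership."""
    deep = np.zeros(cortex_weights.shape, dtype=bool)
    for name, m in deep_gm_rois.items():
        if np.any(m & deep):
            raise ValueError(f"deep-GM ROI {name!r} overlaps another deep-GM ROI")
        deep |= m.astype(bool)
    if np.any((cortex_weights > 0) & deep):
        raise ValueError("cortex weights overlap deep-GM ROIs")
    return np.maximum(cortex_weights, deep.astype(float))


def weighted_roi_mean(
    param_map: np.ndarray,
    weight_map: np.ndarray,
    valid_mask: np.ndarray,
    subject_id: str = "",
    roi: str = "",
    parameter: str = "",
) -> RoiMeasurement:
    """Weight-averaged parameter over valid voxels; empty ROIs are flagged."""
    w = np.where(valid_mask, weight_map, 0.0)
    wsum = float(w.sum())
    n = int(np.count_nonzero(w))
    mean = float((w * param_map).sum() / wsum) if wsum > 0 else float("nan")
    return RoiMeasurement(subject_id, roi, parameter, mean, wsum, n)


def extract_rois(
    maps: QuantitativeMapSet,
    gm_pve: np.ndarray,
    wm_pve: np.ndarray,
    csf_pve_or_mask: np.ndarray,
    deep_gm_masks: dict[str, np.ndarray],
    ventricle_mask: np.ndarray,
    brain_mask: np.ndarray,
    lesion_mask: np.ndarray,
    cal: FatourosCalibration | None = None,
    thresholds: RoiThresholds | None = None,
    cerebellum_mask: np.ndarray | None = None,
) -> RoiSet:
    """Assemble the full ROI set for one subject."""
    if thresholds is None:
        thresholds = RoiThresholds()
    wm_mask = wm_pve >= thresholds.wm_pve_min
    excl = cortex_exclusion_mask(deep_gm_masks, wm_mask, ventricle_mask, cerebellum_mask)
    cortex = build_cortex_pve(gm_pve, maps.t1, excl, lesion_mask, thresholds)
    deep = build_deep_gm_rois(deep_gm_masks, maps.voxel_size, lesion_mask, thresholds)
    deep_union = np.zeros(maps.t1.shape, dtype=bool)
    for m in deep_gm_masks.values():
        deep_union |= m.astype(bool)
    nawm = build_nawm_roi(
        wm_pve, lesion_mask, maps.voxel_size, thresholds, exclusion_mask=deep_union
    )
    wb_t1, wb_pd = build_whole_brain_masks(
        maps.t1, maps.pd, brain_mask, cal, lesion_mask, thresholds
    )
    global_gm = build_global_gm(cortex, deep)
    empty = tuple(
        name
        for name, arr in [("cortex", cortex), ("nawm", nawm), ("nagm", global_gm)]
        + [(k, v) for k, v in deep.items()]
        if not np.any(arr)
    )
    return RoiSet(
        cortex=cortex,
        thalamus=deep["thalamus"],
        caudate=deep["caudate"],
        putamen=deep["putamen"],
        pallidum=deep["pallidum"],
        nawm=nawm,
        whole_brain_t1=wb_t1,
        whole_brain_pd=wb_pd,
        global_gm=global_gm,
        voxel_size=maps.voxel_size,
        empty_rois=empty,
    )


def measure_subject(
    subject_id: str, maps: QuantitativeMapSet, rois: RoiSet
) -> list[RoiMeasurement]:
    """Weighted T1 and PD means for every ROI of one subject."""
    out = []
    for roi in ROI_NAMES:
        for parameter in ("t1", "pd"):
            pmap = maps.t1 if parameter == "t1" else maps.pd
            out.append(
                weighted_roi_mean(
                    pmap, rois.weights(roi, parameter), maps.valid_mask,
                    subject_id, roi, parameter,
                )
            )
    return out


def measurements_table(measurements: list[RoiMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "roi": m.roi,
                "parameter": m.parameter,
                "mean": m.mean,
                "weight_sum": m.weight_sum,
                "n_voxels": m.n_voxels,
            }
            for m in measurements
        ]
    )
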