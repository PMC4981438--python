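"""Synthetic MP-RAGE anatomies, brain masks, PVE segmentation, deep-GM labels.

A T1-weighted anatomical volume is computed voxelwise from the
quantitative T1 and PD maps with the inversion-recovery closed form

    S = pd * (1 - 2 exp(-TI/T1) + exp(-TR/T1)),

with no T2* factor: the input maps are already corrected, so the
nominal TE of the synthetic volume is zero.  Because the anatomy is
computed from the maps themselves it shares their voxel grid exactly
and no registration exists anywhere in the pipeline.

Tissue partial-volume estimates (PVE) come from a three-class Gaussian
mixture on in-brain intensities (an intensity-only stand-in for an
external segmentation tool; externally produced PVE maps can be
supplied instead).  On a magnitude MP-RAGE the components map to
CSF/GM/WM by ascending mean intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from qgm.phantom import DEEP_GM, TISSUE_LABELS

__all__ = [
    "MprageParams",
    "PveMaps",
    "synthesize_mprage",
    "brain_mask_from_labels",
    "validate_external_mask",
    "segment_pve",
    "deep_gm_labels",
    "DEFAULT_SUBCORTICAL_CODES",
]


@dataclass(frozen=True)
class MprageParams:
    tr: float = 1900.0  # ms
    ti: float = 900.0  # ms
    alpha: float = 9.0  # degrees (protocol fact; not in the closed form)
    te: float = 0.0  # nominal; inputs are already T2*-corrected

    def __post_init__(self) -> None:
        if not (0 < self.ti < self.tr):
            raise ValueError("inversion time must satisfy 0 < TI < TR")


@dataclass
class PveMaps:
    """GM/WM/CSF partial-volume estimates in [0, 1], summing to <= 1 in-brain."""

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    source: str = "internal"  # 'internal' | 'external'

    def __post_init__(self) -> None:
        for name, vol in (("gm", self.gm), ("wm", self.wm), ("csf", self.csf)):
            if np.any(vol < -1e-6) or np.any(vol > 1 + 1e-6):
                raise ValueError(f"{name} PVE values must lie in [0, 1]")
        if self.gm.shape != self.wm.shape or self.gm.shape != self.csf.shape:
            raise ValueError("PVE maps must share one grid")
        total = self.gm + self.wm + self.csf
        if np.any(total > 1.0 + 1e-3):
            raise ValueError("PVE maps must sum to at most 1 per voxel")


def synthesize_mprage(
    t1: np.ndarray,
    pd: np.ndarray,
    params: MprageParams | None = None,
    signed: bool = False,
) -> np.ndarray:
    """Synthetic MP-RAGE from quantitative maps (magnitude by default).

    Voxels with non-positive T1 (background, failed fits) map to 0.
    """
    if params is None:
        params = MprageParams()
    if t1.shape != pd.shape:
        raise ValueError("t1 and pd must share one grid")
    ok = t1 > 0
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        safe_t1 = np.where(ok, t1, 1.0)
        s = pd * (1.0 - 2.0 * np.exp(-params.ti / safe_t1) + np.exp(-params.tr / safe_t1))
    s = np.where(ok, s, 0.0)
    return s if signed else np.abs(s)


def brain_mask_from_labels(labels: np.ndarray) -> np.ndarray:
    """Internal skull-stripping stand-in: union of non-background labels."""
    mask = labels > 0
    if not mask.any():
        raise ValueError("label volume contains no brain voxels")
    return mask


def validate_external_mask(mask: np.ndarray, reference_shape: tuple[int, ...]) -> np.ndarray:
    if mask.shape != tuple(reference_shape):
        raise ValueError(f"external mask grid {mask.shape} != data grid {reference_shape}")
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("external mask is empty")
    return mask


def segment_pve(
    anatomy: np.ndarray,
    brain_mask: np.ndarray,
    k: int = 3,
    seed: int = 0,
    max_iter: int = 500,
) -> PveMaps:
    """Three-class Gaussian-mixture PVE segmentation of in-brain intensities.

    EM at a fixed seed, initialized from an Otsu partition of the
    in-brain intensity histogram (the CSF class can be a sub-percent
    volume fraction, which generic k-means initialization tends to miss
    in favour of splitting the large WM mode; Otsu's criterion isolates
    the distant dark tail reliably); posterior responsibilities are the
    PVEs.  Components are assigned to CSF < GM < WM by ascending mean
    intensity (magnitude MP-RAGE ordering).  Raises on non-convergence.
    """
    from skimage.filters import threshold_multiotsu, threshold_otsu

    if anatomy.shape != brain_mask.shape:
        raise ValueError("anatomy and brain mask must share one grid")
    intensities = anatomy[brain_mask].reshape(-1, 1)
    if intensities.shape[0] < 10 * k:
        raise ValueError("too few in-brain voxels to segment")
    flat = intensities.ravel()
    if k == 3:
        # hierarchical Otsu: the GM|WM valley first, then CSF|GM within
        # the darker part.  A single 3-class criterion can prefer
        # splitting the massive WM mode over isolating the tiny CSF
        # class; the two-step split is robust to class imbalance.
        cut_hi = threshold_otsu(flat)
        cut_lo = threshold_otsu(flat[flat < cut_hi])
        cuts = np.array([cut_lo, cut_hi])
    else:
        cuts = threshold_multiotsu(flat, classes=k)
    bins = np.digitize(flat, cuts)
    means_init = np.array([[flat[bins == i].mean()] for i in range(k)])
    weights_init = np.array([(bins == i).mean() for i in range(k)])
    # initial variances from the same partition (floored: a noiseless
    # phantom class can be a zero-variance intensity spike), so the EM
    # starts from a self-consistent parameter set
    var_floor = max(1e-6 * float(flat.var()), 1e-12)
    vars_init = np.array(
        [max(float(flat[bins == i].var()), var_floor) for i in range(k)]
    )
    gmm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        means_init=means_init,
        weights_init=weights_init,
        precisions_init=(1.0 / vars_init).reshape(k, 1, 1),
        max_iter=max_iter,
        random_state=seed,
        reg_covar=var_floor,
    )
    gmm.fit(intensities)
    if not gmm.converged_:
        raise RuntimeError(
            f"EM did not converge within {max_iter} iterations "
            f"(lower bound {gmm.lower_bound_:.6g})"
        )
    resp = gmm.predict_proba(intensities)
    order = np.argsort(gmm.means_.ravel())  # CSF darkest ... WM brightest
    maps = {}
    for idx, name in zip(order, ("csf", "gm", "wm")):
        vol = np.zeros(anatomy.shape, dtype=np.float64)
        vol[brain_mask] = resp[:, idx]
        maps[name] = vol
    return PveMaps(gm=maps["gm"], wm=maps["wm"], csf=maps["csf"], source="internal")


# common subcortical labeling convention (left/right code pairs per structure)
DEFAULT_SUBCORTICAL_CODES: dict[str, tuple[int, ...]] = {
    "thalamus": (10, 49),
    "caudate": (11, 50),
    "putamen": (12, 51),
    "pallidum": (13, 52),
}


def deep_gm_labels(
    labels: np.ndarray,
    code_map: dict[str, tuple[int, ...]] | None = None,
) -> dict[str, np.ndarray]:
    """Per-structure binary masks with hemispheres combined.

    Internal mode (default ``code_map``: the phantom's own codes) reads
    the truth label volume; external mode accepts a subcortical label
    file with a configurable code table mapping one or more integer
    codes (typically a left/right pair) to each of the four structures.
    """
    if code_map is None:
        code_map = {name: (TISSUE_LABELS[name],) for name in DEEP_GM}
    out: dict[str, np.ndarray] = {}
    for name in DEEP_GM:
        if name not in code_map:
            raise ValueError(f"label code map lacks structure {name!r}")
        mask = np.isin(labels, list(code_map[name]))
        if not mask.any():
            raise ValueError(f"deep gray-matter structure {name!r} missing from label volume")
        out[name] = mask
    return out
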