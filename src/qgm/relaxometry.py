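"""Estimation of B1, T2*, T1 and PD maps from the simulated acquisitions.

The processing chain mirrors the acquisition physics:

1. **B1** from the magnetization-prepared pair: the voxelwise quotient
   prepared/reference equals the cosine of the locally realized
   preparation angle, so ``b1 = arccos(quotient) / nominal_angle``.
2. **T2*** from the dual-echo pair: ``(te2 - te1) / ln(s1/s2)``.
3. **T1** from the variable-flip-angle pair by the linearized spoiled
   gradient-echo fit: plotting S_i/tan(a_i) against S_i/sin(a_i) (with
   B1-corrected angles) makes the signal equation a straight line whose
   slope is E1 = exp(-TR/T1); with two angles the fit is closed-form.
4. **PD** from the fit amplitude after T2* and receive-sensitivity
   correction, normalized so the CSF reference region reads 100 pu.

The receive-sensitivity field is either supplied (oracle mode) or
estimated by dividing the corrected amplitude by the water content the
Fatouros relation predicts from the voxel's T1, and fitting a smooth
low-order 3D polynomial to the quotient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = [
    "QuantitativeMapSet",
    "FatourosCalibration",
    "SpoilingCorrection",
    "compute_b1_map",
    "compute_t2star_map",
    "fit_t1_vfa",
    "apply_spoiling_correction",
    "fatouros_water_content",
    "csf_pd_threshold",
    "estimate_receive_bias",
    "derive_pd_map",
    "map_subject",
]


@dataclass
class QuantitativeMapSet:
    """Estimated parameter maps sharing one grid, with a validity mask."""

    t1: np.ndarray  # ms
    pd: np.ndarray  # pu
    b1: np.ndarray  # dimensionless
    t2star: np.ndarray  # ms
    valid_mask: np.ndarray  # bool: voxels where all fits succeeded
    voxel_size: float  # mm

    def __post_init__(self) -> None:
        shapes = {v.shape for v in (self.t1, self.pd, self.b1, self.t2star, self.valid_mask)}
        if len(shapes) != 1:
            raise ValueError("all maps must share one grid")


@dataclass(frozen=True)
class FatourosCalibration:
    """Water content vs. T1: W(T1) = 1 / (a + b / T1), W in [0, 1].

    The default 3 T calibration is fixed by two anchors: W = 1 (100 pu)
    at the CSF T1 of 4300 ms, and W = 0.8444 at T1 = 1600 ms — the pair
    used to convert the whole-brain T1 cutoff into a PD cutoff.  Solving
    the 2x2 linear system for (a, b) gives the constants below.
    """

    a: float = 0.8908012702422935  # dimensionless
    b: float = 469.55453795813816  # ms
    t1_csf_anchor: float = 4300.0  # ms

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("b must be positive for W(t1) to increase with t1")
        anchor_w = 1.0 / (self.a + self.b / self.t1_csf_anchor)
        if abs(anchor_w - 1.0) > 1e-9:
            raise ValueError("calibration must satisfy W(t1_csf_anchor) = 1")

    @classmethod
    def from_anchors(
        cls, t1_csf: float = 4300.0, t1_ref: float = 1600.0, w_ref: float = 0.8444
    ) -> "FatourosCalibration":
        """Solve a + b/t1 = 1/W at the two anchor points."""
        m = np.array([[1.0, 1.0 / t1_csf], [1.0, 1.0 / t1_ref]])
        rhs = np.array([1.0, 1.0 / w_ref])
        a, b = np.linalg.solve(m, rhs)
        return cls(a=float(a), b=float(b), t1_csf_anchor=float(t1_csf))


def fatouros_water_content(
    t1: np.ndarray | float, cal: FatourosCalibration | None = None
) -> np.ndarray | float:
    """Water content in pu predicted from T1 (ms); strictly increasing."""
    if cal is None:
        cal = FatourosCalibration()
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be positive")
    w = 100.0 / (cal.a + cal.b / t1)
    return float(w) if w.ndim == 0 else w


def csf_pd_threshold(
    cal: FatourosCalibration | None = None, t1_cutoff: float = 1600.0
) -> float:
    """PD (pu) equivalent of the whole-brain T1 cutoff via the water relation."""
    return float(fatouros_water_content(t1_cutoff, cal))


@dataclass(frozen=True)
class SpoilingCorrection:
    """Polynomial hook mapping (apparent T1, B1) to corrected T1.

    ``coeffs`` maps exponent pairs (i, j) to coefficients of
    t1_app^i * b1^j; the identity is {(1, 0): 1.0}.  The simulator
    spoils ideally, so the default correction is the identity;
    coefficients for a real protocol can be loaded from config.
    """

    coeffs: dict[tuple[int, int], float] = field(default_factory=lambda: {(1, 0): 1.0})

    @property
    def is_identity(self) -> bool:
        return self.coeffs == {(1, 0): 1.0}

    @classmethod
    def from_scale(cls, scale: float) -> "SpoilingCorrection":
        return cls({(1, 0): float(scale)})

    def to_dict(self) -> dict:
        return {f"{i},{j}": c for (i, j), c in self.coeffs.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "SpoilingCorrection":
        coeffs = {}
        for key, c in d.items():
            i, j = (int(p) for p in str(key).split(","))
            coeffs[(i, j)] = float(c)
        return cls(coeffs)


def apply_spoiling_correction(
    t1_app: np.ndarray, b1: np.ndarray, corr: SpoilingCorrection | None = None
) -> np.ndarray:
    if corr is None or corr.is_identity:
        return np.array(t1_app, copy=True)
    out = np.zeros_like(np.asarray(t1_app, dtype=float))
    for (i, j), c in corr.coeffs.items():
        out += c * np.asarray(t1_app, float) ** i * np.asarray(b1, float) ** j
    return out


def compute_b1_map(
    s_ref: np.ndarray,
    s_prep: np.ndarray,
    nominal_prep_angle: float = 45.0,
    noise_floor: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """B1 map from the prepared/reference quotient.

    Returns (b1, valid).  The quotient is clamped to [-1, 1] before the
    arccos; voxels whose reference signal falls below ``noise_floor``
    times the robust (99th-percentile) reference maximum are invalid.
    """
    if s_ref.shape != s_prep.shape:
        raise ValueError("B1 pair volumes must share one grid")
    if not (0.0 < nominal_prep_angle < 90.0):
        raise ValueError("nominal preparation angle must lie in (0, 90) degrees")
    ref_scale = np.percentile(np.abs(s_ref), 99)
    floor = noise_floor * ref_scale if ref_scale > 0 else 0.0
    safe_ref = np.where(np.abs(s_ref) > floor, s_ref, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.clip(s_prep / safe_ref, -1.0, 1.0)
        b1 = np.arccos(ratio) / np.deg2rad(nominal_prep_angle)
    valid = np.isfinite(b1)
    b1 = np.where(valid, b1, 0.0)
    return b1, valid


def compute_t2star_map(
    s_te1: np.ndarray, s_te2: np.ndarray, te1: float, te2: float
) -> tuple[np.ndarray, np.ndarray]:
    """T2* (ms) from the dual-echo log-ratio.

    Returns (t2star, valid).  Equal echoes give infinite T2* (no decay;
    handled, not an error); non-positive or non-finite results — e.g.
    the second echo exceeding the first through noise — are invalid.
    """
    if te2 <= te1:
        raise ValueError("te2 must exceed te1")
    if s_te1.shape != s_te2.shape:
        raise ValueError("dual-echo volumes must share one grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log(s_te1 / s_te2)
        t2star = np.where(log_ratio == 0.0, np.inf, (te2 - te1) / log_ratio)
    valid = (np.nan_to_num(t2star, nan=-1.0) > 0) | np.isposinf(t2star)
    t2star = np.where(valid, t2star, 0.0)
    return t2star, valid


def fit_t1_vfa(
    s_pdw: np.ndarray,
    s_t1w: np.ndarray,
    alpha1: float,
    alpha2: float,
    b1: np.ndarray,
    tr: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form two-point variable-flip-angle T1 fit.

    With B1-corrected angles, x_i = S_i/tan(a_i) and y_i = S_i/sin(a_i)
    lie on the line y = E1 x + M (1 - E1) where E1 = exp(-TR/T1) and M
    is the T1-free signal amplitude (pd times receive sensitivity times
    the TE decay).  Returns (t1_app ms, m0_app, valid); voxels whose
    slope falls outside (0, 1) or with degenerate abscissae are invalid.
    """
    if s_pdw.shape != s_t1w.shape or s_pdw.shape != np.shape(b1):
        raise ValueError("VFA volumes and B1 map must share one grid")
    a1 = np.deg2rad(alpha1) * np.asarray(b1, float)
    a2 = np.deg2rad(alpha2) * np.asarray(b1, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        x1 = s_pdw / np.tan(a1)
        y1 = s_pdw / np.sin(a1)
        x2 = s_t1w / np.tan(a2)
        y2 = s_t1w / np.sin(a2)
        dx = x2 - x1
        slope = np.where(dx != 0, (y2 - y1) / np.where(dx != 0, dx, 1.0), np.nan)
        valid = np.isfinite(slope) & (slope > 0.0) & (slope < 1.0)
        t1_app = np.where(valid, -tr / np.log(np.where(valid, slope, 0.5)), 0.0)
        intercept = y1 - slope * x1
        m0_app = np.where(valid, intercept / (1.0 - np.where(valid, slope, 0.5)), 0.0)
    valid = valid & (t1_app > 0)
    return t1_app, m0_app, valid


def _poly_design(shape: tuple[int, ...], order: int) -> np.ndarray:
    """Monomial basis x^i y^j z^k, i+j+k <= order, on [-1, 1]^3 coordinates."""
    axes = [np.linspace(-1.0, 1.0, s) for s in shape]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    cols = [
        (x**i * y**j * z**k).ravel()
        for i, j, k in product(range(order + 1), repeat=3)
        if i + j + k <= order
    ]
    return np.column_stack(cols)


def estimate_receive_bias(
    amp_corrected: np.ndarray,
    t1: np.ndarray,
    brain_mask: np.ndarray,
    cal: FatourosCalibration | None = None,
    order: int = 3,
    fit_mask: np.ndarray | None = None,
    known_field: np.ndarray | None = None,
) -> np.ndarray:
    """Smooth receive-sensitivity field over the whole grid.

    The T1/T2*/B1-corrected signal amplitude is divided by the water
    content the Fatouros relation predicts from T1; the quotient is, up
    to a global scale (which the CSF normalization later cancels), the
    receive field times the tissue's deviation from the water-T1
    relation.  A low-order 3D polynomial least-squares fit within
    ``fit_mask`` (default: the brain mask) smooths away tissue structure
    and returns the field over the whole grid.  In oracle mode a known
    field bypasses estimation and is returned unchanged.
    """
    if known_field is not None:
        if known_field.shape != amp_corrected.shape:
            raise ValueError("known receive field has mismatched grid")
        return np.array(known_field, copy=True)
    if cal is None:
        cal = FatourosCalibration()
    mask = brain_mask if fit_mask is None else fit_mask
    mask = mask & (t1 > 0) & np.isfinite(amp_corrected)
    design = _poly_design(amp_corrected.shape, order)
    n_coef = design.shape[1]
    if mask.sum() < 2 * n_coef:
        raise ValueError(
            f"too few valid voxels ({int(mask.sum())}) for an order-{order} bias fit"
        )
    w_pred = fatouros_water_content(np.where(t1 > 0, t1, 1.0), cal)
    ratio = amp_corrected / w_pred
    coef, *_ = np.linalg.lstsq(design[mask.ravel()], ratio[mask], rcond=None)
    return (design @ coef).reshape(amp_corrected.shape)


def derive_pd_map(
    m0_app: np.ndarray,
    t2star: np.ndarray,
    receive_field: np.ndarray,
    te: float,
    csf_mask: np.ndarray,
) -> np.ndarray:
    """PD map in pu: undo T2* decay and receive bias, anchor CSF at 100.

    pd_raw = m0_app exp(+te/t2star) / receive_field, then normalized so
    the median within the CSF reference mask is exactly 100 pu (the
    median is robust to tail voxels).  Any global scale in the receive
    field cancels by construction.
    """
    if not np.any(csf_mask):
        raise ValueError("CSF reference mask is empty; cannot normalize PD")
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        decay_inv = np.exp(te / np.where(t2star > 0, t2star, np.inf))
        pd_raw = m0_app * decay_inv / receive_field
    ref = np.median(pd_raw[csf_mask & np.isfinite(pd_raw)])
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError("CSF reference region yields a non-positive PD reference")
    return 100.0 * pd_raw / ref


def map_subject(
    signals: dict[str, np.ndarray],
    protocol,
    csf_mask: np.ndarray,
    brain_mask: np.ndarray,
    voxel_size: float,
    cal: FatourosCalibration | None = None,
    spoiling: SpoilingCorrection | None = None,
    oracle_receive: np.ndarray | None = None,
    b1_window: tuple[float, float] = (0.5, 1.5),
    bias_fit_t1_window: tuple[float, float] = (600.0, 1050.0),
    bias_fit_order: int = 3,
) -> QuantitativeMapSet:
    """Run the full mapping chain on one subject's six contrast volumes.

    ``bias_fit_t1_window`` restricts the receive-bias polynomial fit to
    a narrow T1 range (white-matter-dominated voxels) so that
    tissue-specific deviations from the water-T1 relation are nearly
    constant there and cancel in the CSF normalization; the smooth
    polynomial extrapolates the field to the rest of the brain.
    """
    if cal is None:
        cal = FatourosCalibration()
    vfa = protocol.vfa
    b1, b1_valid = compute_b1_map(
        signals["b1ref"], signals["b1prep"], protocol.b1map.nominal_prep_angle
    )
    t2star, t2_valid = compute_t2star_map(
        signals["te1"], signals["te2"], protocol.dual_echo.te1, protocol.dual_echo.te2
    )
    t1_app, m0_app, t1_valid = fit_t1_vfa(
        signals["pdw"], signals["t1w"], vfa.alpha1, vfa.alpha2, b1, vfa.tr
    )
    t1 = apply_spoiling_correction(t1_app, b1, spoiling)

    with np.errstate(over="ignore"):
        amp_corr = m0_app * np.exp(vfa.te / np.where(t2star > 0, t2star, np.inf))
    lo, hi = bias_fit_t1_window
    fit_mask = brain_mask & t1_valid & t2_valid & (t1 >= lo) & (t1 <= hi)
    try:
        receive = estimate_receive_bias(
            amp_corr, t1, brain_mask, cal,
            order=bias_fit_order, fit_mask=fit_mask, known_field=oracle_receive,
        )
    except ValueError:
        # fall back to the whole brain if the T1 window is too sparse
        receive = estimate_receive_bias(
            amp_corr, t1, brain_mask, cal,
            order=bias_fit_order, fit_mask=brain_mask & t1_valid & t2_valid,
            known_field=oracle_receive,
        )
    pd = derive_pd_map(m0_app, t2star, receive, vfa.te, csf_mask)

    valid = (
        brain_mask
        & b1_valid
        & t2_valid
        & t1_valid
        & (b1 >= b1_window[0])
        & (b1 <= b1_window[1])
        & (t1 > 0)
        & (pd > 0)
        & np.isfinite(pd)
    )
    return QuantitativeMapSet(
        t1=t1, pd=pd, b1=b1, t2star=t2star, valid_mask=valid, voxel_size=voxel_size
    )
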