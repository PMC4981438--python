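"""Digital brain phantoms and two-group cohorts with known tissue parameters.

The phantom is deliberately geometric rather than anatomical: a brain
envelope ellipsoid with a cortical ribbon shell, a white-matter core,
paired ventricles filled with CSF, four paired deep gray-matter
ellipsoids (thalamus, caudate, putamen, pallidum) and optional
white-matter lesions.  The scientific claims exercised downstream are
parameter-level (tissue T1 and proton density and their group/disability
statistics), not shape-level, so analytic shapes suffice and make every
ground-truth quantity exact.

Tissue T1 (ms) and PD (percent units, CSF = 100) are drawn per subject
from group-specific Gaussians; patients additionally receive a linear
disability link: gray-matter tissue values are shifted by a configurable
slope times the subject's centred EDSS score, which generates the
monotone qMRI-disability association the analysis stage is designed to
detect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TISSUE_LABELS",
    "GM_LINK_TISSUES",
    "TissueSpec",
    "PhantomGeometry",
    "SubjectTruth",
    "CohortSpec",
    "PhantomConfigError",
    "build_phantom_geometry",
    "draw_subject_parameters",
    "sample_subject",
    "generate_cohort",
    "default_tissue_table",
    "covariate_table",
    "write_subject",
]

# integer label codes used in every label volume (0 = background)
TISSUE_LABELS: dict[str, int] = {
    "csf": 1,
    "cortex": 2,
    "wm": 3,
    "thalamus": 4,
    "caudate": 5,
    "putamen": 6,
    "pallidum": 7,
    "lesion": 8,
}

DEEP_GM = ("thalamus", "caudate", "putamen", "pallidum")
# tissues whose parameters are shifted by the disability link in patients
GM_LINK_TISSUES = ("cortex",) + DEEP_GM


class PhantomConfigError(ValueError):
    """Raised when a phantom geometry cannot be realized on the grid."""


@dataclass(frozen=True)
class TissueSpec:
    """Population distribution of one tissue class.

    t1/pd means and SDs parameterize per-subject Gaussian draws; t2star
    is a fixed sequence-level constant per tissue (no population model).
    PD is expressed in percent units (pu) relative to CSF water = 100.
    """

    name: str
    t1_mean: float
    t1_sd: float
    pd_mean: float
    pd_sd: float
    t2star: float

    def __post_init__(self) -> None:
        if self.name not in TISSUE_LABELS:
            raise ValueError(f"unknown tissue name {self.name!r}")
        if self.t1_mean <= 0:
            raise ValueError(f"{self.name}: t1_mean must be positive")
        if self.t2star <= 0:
            raise ValueError(f"{self.name}: t2star must be positive")
        if self.name == "csf":
            if self.pd_mean != 100.0:
                raise ValueError("CSF pd_mean must be exactly 100 pu")
        elif not (0.0 < self.pd_mean <= 100.0):
            raise ValueError(f"{self.name}: pd_mean must be in (0, 100]")
        if self.t1_sd < 0 or self.pd_sd < 0:
            raise ValueError(f"{self.name}: SDs must be non-negative")


def default_tissue_table(group: str) -> dict[str, TissueSpec]:
    """Per-tissue population values for one group.

    Gray/white-matter means and SDs follow published 3 T cohort values
    for secondary-progressive MS patients and matched healthy controls;
    CSF anchors the PD scale at exactly 100 pu with a long T1.  T2*
    values are representative 3 T magnitudes (short in the iron-rich
    pallidum, long in CSF).
    """
    if group == "patient":
        rows = {
            "csf": (4300.0, 0.0, 100.0, 0.0, 500.0),
            "cortex": (1425.9, 27.09, 83.8, 1.91, 66.0),
            "wm": (911.0, 41.16, 71.7, 2.49, 53.0),
            "thalamus": (1252.6, 83.98, 78.7, 2.01, 58.0),
            "caudate": (1326.7, 48.93, 81.8, 2.51, 55.0),
            "putamen": (1264.5, 54.64, 82.5, 2.91, 45.0),
            "pallidum": (1003.4, 49.08, 77.1, 2.63, 30.0),
            "lesion": (1700.0, 60.0, 88.0, 2.0, 70.0),
        }
    elif group == "control":
        rows = {
            "csf": (4300.0, 0.0, 100.0, 0.0, 500.0),
            "cortex": (1403.0, 15.93, 80.8, 1.67, 66.0),
            "wm": (865.8, 28.75, 67.9, 1.68, 53.0),
            "thalamus": (1184.4, 54.55, 75.6, 2.60, 58.0),
            "caudate": (1343.1, 43.30, 80.2, 2.01, 55.0),
            "putamen": (1278.6, 39.96, 79.7, 1.69, 45.0),
            "pallidum": (1016.2, 42.15, 74.4, 1.76, 30.0),
            "lesion": (1700.0, 60.0, 88.0, 2.0, 70.0),
        }
    else:
        raise ValueError(f"group must be 'patient' or 'control', got {group!r}")
    return {
        name: TissueSpec(name, t1m, t1s, pdm, pds, t2s)
        for name, (t1m, t1s, pdm, pds, t2s) in rows.items()
    }


@dataclass(frozen=True)
class _Structure:
    """A paired (or single) ellipsoidal structure placed in mm."""

    center_mm: tuple[float, float, float]  # offset from grid centre; x mirrored for pairs
    axes_mm: tuple[float, float, float]
    paired: bool = True


@dataclass(frozen=True)
class PhantomGeometry:
    """Grid and structure placement for the analytic phantom.

    All placements are specified in millimetres so the same geometry
    realizes on the desk-scale 64 cubed / 2 mm grid and on a 1 mm
    protocol-resolution grid alike.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 2.0  # mm, isotropic
    envelope_axes_mm: tuple[float, float, float] = (52.0, 48.0, 44.0)
    cortex_inner_scale: float = 0.86  # inner-ellipsoid scale; shell = cortical ribbon
    ventricles: _Structure = _Structure((10.0, -2.0, 4.0), (5.0, 14.0, 7.0))
    thalamus: _Structure = _Structure((22.0, -10.0, 0.0), (7.0, 8.0, 6.0))
    caudate: _Structure = _Structure((14.0, 16.0, 12.0), (5.0, 8.0, 5.0))
    putamen: _Structure = _Structure((34.0, 4.0, 0.0), (5.0, 10.0, 8.0))
    pallidum: _Structure = _Structure((22.0, 8.0, -4.0), (4.0, 5.0, 4.0))
    lesion_count: int = 3
    lesion_radius_mm: tuple[float, float] = (2.0, 4.0)

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise PhantomConfigError("voxel_size must be positive")
        if any(s <= 0 for s in self.grid_shape):
            raise PhantomConfigError("grid_shape entries must be positive")
        if not (0 < self.cortex_inner_scale < 1):
            raise PhantomConfigError("cortex_inner_scale must be in (0, 1)")
        if self.lesion_count < 0:
            raise PhantomConfigError("lesion_count must be non-negative")


@dataclass
class SubjectTruth:
    """Ground truth for one simulated subject."""

    subject_id: str
    group: str  # 'patient' | 'control'
    labels: np.ndarray  # integer label volume, 0 = background
    true_t1: np.ndarray  # ms
    true_pd: np.ndarray  # pu
    true_t2star: np.ndarray  # ms
    lesion_mask: np.ndarray  # bool
    voxel_size: float  # mm
    edss: float | None  # patients only
    age: float
    sex: int  # 1 = male, 0 = female
    disease_duration: float  # years; 0 for controls
    tissue_values: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level configuration: group sizes, tissue tables, EDSS model."""

    n_per_group: int = 11
    patient_tissues: dict[str, TissueSpec] = field(
        default_factory=lambda: default_tissue_table("patient")
    )
    control_tissues: dict[str, TissueSpec] = field(
        default_factory=lambda: default_tissue_table("control")
    )
    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)
    edss_mean: float = 5.8
    edss_sd: float = 1.88
    edss_min: float = 3.0
    edss_max: float = 8.5
    # disability link: GM tissue shift per EDSS point (ms, pu); chosen so the
    # population Spearman correlation between EDSS and cortical values is ~0.7
    link_slope_t1: float = 14.0
    link_slope_pd: float = 1.0
    link_noise_sd_t1: float = 0.0
    link_noise_sd_pd: float = 0.0
    age_mean: float = 45.0
    age_sd: float = 11.0
    duration_mean: float = 15.3
    duration_sd: float = 6.75
    male_fraction_patients: float = 4.0 / 11.0
    male_fraction_controls: float = 5.0 / 11.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.edss_min > self.edss_max:
            raise ValueError("edss_min must not exceed edss_max")

    def tissues(self, group: str) -> dict[str, TissueSpec]:
        if group == "patient":
            return self.patient_tissues
        if group == "control":
            return self.control_tissues
        raise ValueError(f"unknown group {group!r}")


# ---------------------------------------------------------------------------
# geometry realization


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center_vox: np.ndarray,
    axes_vox: np.ndarray,
) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center_vox, axes_vox))
    return d <= 1.0


def _structure_mask(geom: PhantomGeometry, struct: _Structure) -> np.ndarray:
    shape = geom.grid_shape
    centre = (np.asarray(shape, float) - 1.0) / 2.0
    off = np.asarray(struct.center_mm) / geom.voxel_size
    axes = np.asarray(struct.axes_mm) / geom.voxel_size
    mask = _ellipsoid_mask(shape, centre + off, axes)
    if struct.paired:
        mirrored = off.copy()
        mirrored[0] = -mirrored[0]
        mask = mask | _ellipsoid_mask(shape, centre + mirrored, axes)
    return mask


def build_phantom_geometry(geometry: PhantomGeometry, seed: int = 0) -> np.ndarray:
    """Realize the analytic geometry as an integer label volume.

    Structures are painted in priority order inside the white-matter
    core (ventricles first, then the four deep-GM pairs, then lesions).
    Any structure that leaves the core or collides with an earlier one
    raises :class:`PhantomConfigError` naming the offender.
    """
    shape = geometry.grid_shape
    centre = (np.asarray(shape, float) - 1.0) / 2.0
    env_axes = np.asarray(geometry.envelope_axes_mm) / geometry.voxel_size
    if np.any(env_axes >= np.asarray(shape) / 2.0):
        raise PhantomConfigError("brain envelope does not fit inside the grid")
    envelope = _ellipsoid_mask(shape, centre, env_axes)
    inner = _ellipsoid_mask(shape, centre, geometry.cortex_inner_scale * env_axes)

    labels = np.zeros(shape, dtype=np.uint8)
    labels[envelope & ~inner] = TISSUE_LABELS["cortex"]
    labels[inner] = TISSUE_LABELS["wm"]

    claimed = np.zeros(shape, dtype=bool)
    for name in ("ventricles",) + DEEP_GM:
        struct: _Structure = getattr(geometry, "ventricles" if name == "ventricles" else name)
        mask = _structure_mask(geometry, struct)
        if not mask.any():
            raise PhantomConfigError(f"structure {name!r} is empty on this grid")
        if np.any(mask & ~inner):
            raise PhantomConfigError(f"structure {name!r} extends outside the white-matter core")
        if np.any(mask & claimed):
            raise PhantomConfigError(f"structure {name!r} overlaps a previously placed structure")
        code = TISSUE_LABELS["csf"] if name == "ventricles" else TISSUE_LABELS[name]
        labels[mask] = code
        claimed |= mask

    if geometry.lesion_count > 0:
        _place_lesions(labels, geometry, seed)
    return labels


def _place_lesions(labels: np.ndarray, geom: PhantomGeometry, seed: int) -> None:
    """Carve spherical lesions fully inside plain white matter."""
    rng = np.random.default_rng(seed)
    wm = labels == TISSUE_LABELS["wm"]
    shape = labels.shape
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    placed = 0
    attempts = 0
    max_attempts = 200 * max(1, geom.lesion_count)
    wm_idx = np.argwhere(wm)
    while placed < geom.lesion_count:
        attempts += 1
        if attempts > max_attempts:
            raise PhantomConfigError(
                f"could not place lesion {placed + 1} of {geom.lesion_count} "
                "inside white matter"
            )
        r_mm = rng.uniform(*geom.lesion_radius_mm)
        r_vox = r_mm / geom.voxel_size
        c = wm_idx[rng.integers(len(wm_idx))]
        sphere = sum(((g - ci) / r_vox) ** 2 for g, ci in zip(grids, c)) <= 1.0
        if not sphere.any():
            continue
        # the whole sphere must sit in still-unclaimed WM
        if np.any(sphere & (labels != TISSUE_LABELS["wm"])):
            continue
        labels[sphere] = TISSUE_LABELS["lesion"]
        placed += 1


# ---------------------------------------------------------------------------
# subject and cohort sampling

_MAX_REDRAWS = 1000


def _draw_positive(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        if mean <= 0:
            raise ValueError("configured mean must be positive when sd = 0")
        return mean
    for _ in range(_MAX_REDRAWS):
        v = rng.normal(mean, sd)
        if v > 0:
            return v
    raise RuntimeError(f"failed to draw a positive value from N({mean}, {sd}^2)")


def _draw_edss(rng: np.random.Generator, spec: CohortSpec) -> float:
    """Truncated-Gaussian EDSS, rejection-sampled, rounded to 0.5 steps."""
    for _ in range(_MAX_REDRAWS):
        v = rng.normal(spec.edss_mean, spec.edss_sd)
        if spec.edss_min <= v <= spec.edss_max:
            return float(np.round(v * 2.0) / 2.0)
    raise RuntimeError("EDSS rejection sampling exceeded the redraw cap")


def draw_subject_parameters(
    cohort: CohortSpec, group: str, rng: np.random.Generator
) -> dict:
    """Draw one subject's covariates and per-tissue parameter scalars.

    This is the truth-level core shared by :func:`sample_subject` (which
    additionally realizes volumes) and the statistical power harness
    (which works on tissue scalars directly).  Patient GM tissues
    (cortex + deep GM) are shifted by ``link_slope * (EDSS - edss_mean)``
    plus optional Gaussian link noise; negative draws of T1 or PD are
    rejected and redrawn.
    """
    tissues = cohort.tissues(group)
    missing = set(TISSUE_LABELS) - set(tissues)
    if missing:
        raise ValueError(f"tissue table for {group!r} lacks: {sorted(missing)}")

    edss = _draw_edss(rng, cohort) if group == "patient" else None
    age = _draw_positive(rng, cohort.age_mean, cohort.age_sd)
    male_frac = (
        cohort.male_fraction_patients if group == "patient" else cohort.male_fraction_controls
    )
    sex = int(rng.random() < male_frac)
    duration = (
        _draw_positive(rng, cohort.duration_mean, cohort.duration_sd)
        if group == "patient"
        else 0.0
    )

    values: dict[str, dict[str, float]] = {}
    for name, spec in tissues.items():
        t1 = _draw_positive(rng, spec.t1_mean, spec.t1_sd)
        pd_ = _draw_positive(rng, spec.pd_mean, spec.pd_sd)
        if group == "patient" and name in GM_LINK_TISSUES:
            delta = edss - cohort.edss_mean
            t1 += cohort.link_slope_t1 * delta
            pd_ += cohort.link_slope_pd * delta
            if cohort.link_noise_sd_t1 > 0:
                t1 += rng.normal(0.0, cohort.link_noise_sd_t1)
            if cohort.link_noise_sd_pd > 0:
                pd_ += rng.normal(0.0, cohort.link_noise_sd_pd)
            t1 = max(t1, 1.0)
            pd_ = min(max(pd_, 1.0), 100.0)
        values[name] = {"t1": t1, "pd": pd_, "t2star": spec.t2star}

    return {
        "values": values,
        "edss": edss,
        "age": age,
        "sex": sex,
        "disease_duration": duration,
    }


def sample_subject(
    cohort: CohortSpec,
    group: str,
    seed: int,
    subject_id: str | None = None,
) -> SubjectTruth:
    """Draw one subject: tissue parameters, covariates, and truth volumes."""
    rng = np.random.default_rng(seed)
    params = draw_subject_parameters(cohort, group, rng)
    values = params["values"]

    geom = cohort.geometry
    if group == "control":
        geom = dataclasses.replace(geom, lesion_count=0)
    lesion_seed = int(rng.integers(2**31 - 1))
    labels = build_phantom_geometry(geom, seed=lesion_seed)

    true_t1 = np.zeros(labels.shape, dtype=np.float64)
    true_pd = np.zeros_like(true_t1)
    true_t2s = np.zeros_like(true_t1)
    for name, code in TISSUE_LABELS.items():
        m = labels == code
        true_t1[m] = values[name]["t1"]
        true_pd[m] = values[name]["pd"]
        true_t2s[m] = values[name]["t2star"]

    if subject_id is None:
        subject_id = f"{group}_{seed:08d}"
    return SubjectTruth(
        subject_id=subject_id,
        group=group,
        labels=labels,
        true_t1=true_t1,
        true_pd=true_pd,
        true_t2star=true_t2s,
        lesion_mask=labels == TISSUE_LABELS["lesion"],
        voxel_size=geom.voxel_size,
        edss=params["edss"],
        age=params["age"],
        sex=params["sex"],
        disease_duration=params["disease_duration"],
        tissue_values=values,
        seed=seed,
    )


def generate_cohort(cohort: CohortSpec) -> list[SubjectTruth]:
    """Generate both groups; per-subject seeds derive from the master seed."""
    ss = np.random.SeedSequence(cohort.seed)
    children = ss.spawn(2 * cohort.n_per_group)
    subjects: list[SubjectTruth] = []
    for i in range(cohort.n_per_group):
        seed = int(children[i].generate_state(1)[0] % (2**31 - 1))
        subjects.append(sample_subject(cohort, "patient", seed, f"patient{i + 1:02d}"))
    for i in range(cohort.n_per_group):
        seed = int(children[cohort.n_per_group + i].generate_state(1)[0] % (2**31 - 1))
        subjects.append(sample_subject(cohort, "control", seed, f"control{i + 1:02d}"))
    return subjects


def covariate_table(subjects: list[SubjectTruth]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": s.subject_id,
            "group": s.group,
            "edss": s.edss if s.edss is not None else np.nan,
            "age": s.age,
            "sex": s.sex,
            "disease_duration": s.disease_duration,
            "seed": s.seed,
        }
        for s in subjects
    ]
    return pd.DataFrame(rows)


def write_subject(subject: SubjectTruth, out_dir: str | Path) -> None:
    """Write truth volumes as NIfTI-1 (labels uint8, maps float32)."""
    from qgm._nifti import save_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = subject.subject_id
    vs = subject.voxel_size
    save_volume(out / f"{sid}_labels.nii.gz", subject.labels.astype(np.uint8), vs)
    save_volume(out / f"{sid}_true_t1.nii.gz", subject.true_t1.astype(np.float32), vs)
    save_volume(out / f"{sid}_true_pd.nii.gz", subject.true_pd.astype(np.float32), vs)
    save_volume(out / f"{sid}_true_t2star.nii.gz", subject.true_t2star.astype(np.float32), vs)
    save_volume(out / f"{sid}_lesions.nii.gz", subject.lesion_mask.astype(np.uint8), vs)
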