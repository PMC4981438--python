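# Methods

This note documents the models, parameter choices and numerical
decisions behind `qgm`, and what the synthetic validation can and
cannot show about real data.

## The digital phantom

The phantom is a set of concentric analytic shapes on a regular grid:
an ellipsoidal brain envelope whose outer shell (inner scale 0.86) is
the cortical ribbon, a white-matter core, paired ventricular
ellipsoids filled with CSF, four mirrored deep-gray ellipsoid pairs
(thalamus, caudate, putamen, pallidum) and, for patients, spherical
white-matter lesions placed rejection-wise fully inside plain WM.
All placements are specified in millimetres, so the default desk-scale
grid (64³ voxels at 2 mm isotropic) and a protocol-resolution override
(e.g. 256×224×160 at 1 mm) realize the same anatomy. The geometry is
deliberately not anatomical: every claim the pipeline tests is
parameter-level (tissue T1/PD statistics), not shape-level, and simple
shapes make ground truth exact. Structure placement is validated at
build time (inside the WM core, pairwise disjoint) and a
`PhantomConfigError` names any structure that does not fit.

Per-subject tissue parameters are scalar per tissue class: T1 and PD
are drawn from group-specific Gaussians whose defaults are published
3 T cohort values for SPMS patients and matched controls (cortex
patients 1425.9 ± 27.1 ms / 83.8 ± 1.91 pu, controls 1403.0 ± 15.9 ms
/ 80.8 ± 1.67 pu, and so on for the deep-GM structures, WM and whole
brain); CSF is fixed at T1 = 4300 ms, PD = 100 pu, anchoring the PD
scale. T2* per tissue is a fixed representative 3 T constant (66 ms
cortex, 53 ms WM, 30 ms in the iron-rich pallidum, 500 ms CSF);
no population model is placed on T2* because it only enters as a
correction factor. Lesions default to T1 1700 ms / PD 88 pu —
long-T1, water-rich tissue that the whole-brain CSF cutoffs happen to
exclude, mirroring their exclusion from every ROI.

**Disability link.** Patients draw EDSS from a Gaussian (mean 5.8,
SD 1.88) truncated by rejection to [3, 8.5] and rounded to the scale's
0.5 steps. Gray-matter tissues (cortex + the four deep-GM structures)
are then shifted linearly: Δ = slope × (EDSS − 5.8), with optional
additive Gaussian link noise. The study this emulates reports observed
rank correlations (≈0.6–0.78) but no generative model; the linear link
is a stand-in whose default slopes (14 ms and 1.0 pu per EDSS point)
were chosen once so that, combined with the tissue SDs above, the
population Spearman correlation between EDSS and cortical values is
≈0.7. The slopes are free generator knobs, not estimates.

Covariates: one shared age distribution (45 ± 11 y) for both groups
(the groups are age-matched by construction), male fractions 4/11 and
5/11, disease duration 15.3 ± 6.75 y for patients. All randomness
flows from one master seed through `numpy.random.SeedSequence`, so a
cohort is byte-reproducible.

## Forward simulation

Three acquisitions are simulated voxelwise from the truth maps on one
common grid: the spoiled gradient-echo VFA pair (TR/TE/α₁/α₂ =
16.4 ms/6.7 ms/4°/24°), the B1 pair (reference ∝ PD × receive field;
prepared = reference × cos(b₁ × 45°)), and the dual-echo pair
(TE 4.3/11 ms). Transmit (B1) inhomogeneity multiplies all nominal
flip angles; receive sensitivity multiplies all signals; both default
fields are low-order polynomials over normalized coordinates with
~±10 % (B1) and ~±20 % (receive) in-brain variation. Noise is
additive Gaussian on magnitude — Rician floor effects are negligible
at the simulated SNRs — with `noise_sd` in the same arbitrary units as
the signal (PD scaled 0–100); the pipeline default is 0.2, roughly
SNR 25–130 depending on contrast.

Simplifications, by design: spoiling is ideal (so the spoiling
correction defaults to identity and is exposed only as a configurable
polynomial hook); all volumes share the map grid rather than the real
protocol's coarser B1/T2* grids (trilinear resampling is available for
externally supplied data); and the longitudinal-relaxation correction
inside the real B1 method is unnecessary here because the simulated
pair has no relaxation confound.

## Map estimation

* **B1**: arccos of the clamped prepared/reference quotient over the
  nominal angle; voxels with reference signal below a noise floor
  (10⁻⁶ of the robust maximum) are invalid; plausibility window
  0.5–1.5 applied in the combined validity mask.
* **T2\***: ΔTE / log-ratio; equal echoes give +∞ (the TE correction
  factor degrades to 1); non-positive results are invalid.
* **T1/amplitude**: closed-form two-point VFA fit (two unknowns, two
  equations — least squares would add nothing); slope outside (0, 1)
  or degenerate abscissae flag the voxel invalid, never raise.
  Flagged voxels are excluded from ROI statistics rather than imputed.
* **Receive field**: the T2*-corrected amplitude divided by the
  Fatouros-predicted water content W(T1) is, within any single tissue,
  exactly the receive field times a constant. Because the phantom's
  tissue PDs deviate from the water–T1 relation by up to ~3 %
  tissue-wise, fitting the quotient over the whole brain would tilt
  the polynomial along the concentric tissue layout; the default fit
  mask is therefore a narrow T1 window (600–1050 ms, WM-dominated),
  where the deviation is nearly constant and cancels in the later CSF
  normalization. An order-3 polynomial (20 monomials on [−1, 1]³
  coordinates, ordinary least squares) extrapolates the field over the
  grid — exact for true polynomial fields of order ≤ 3. A whole-brain
  fallback applies if the window is too sparse, and oracle mode
  accepts the known field directly.
* **PD**: amplitude × e^(+TE/T2\*) / receive field, scaled so the
  median (robust to tail voxels) inside the ventricular CSF mask is
  exactly 100 pu. Any global receive scale cancels.
* **Fatouros calibration**: W(T1) = 1/(a + b/T1) with defaults fixed
  by the two anchors W(4300 ms) = 100 pu and W(1600 ms) = 84.44 pu,
  giving a = 0.8908012702, b = 469.5545380 ms from the 2×2 linear
  system. The published 3 T coefficients this stands in for are
  substitutable through configuration.

## Anatomy synthesis and segmentation

The synthetic MP-RAGE uses the single-exponential inversion-recovery
closed form S = PD (1 − 2e^(−TI/T1) + e^(−TR/T1)) at TR/TI =
1900/900 ms, magnitude by default, TE nominally zero since the input
maps are already T2*-corrected. A readout-train steady-state
simulation is not needed: the anatomy only has to provide consistent
tissue contrast for segmentation, on the maps' own grid (there is no
registration step anywhere).

Segmentation is a three-class Gaussian mixture on in-brain intensities
(intensity-only: the synthesized anatomy has no bias field by
construction). Initialization matters more than usual because CSF is
under 1 % of brain volume here: generic k-means(++) starts, fixed
percentile starts, and single-pass 3-class Otsu all misallocate the
third component to the heavy WM mode on some subjects. The EM is
therefore started from a hierarchical Otsu partition — first the GM|WM
valley, then the CSF|GM cut within the darker part — supplying
consistent means, weights and (floored) variances; the variance floor
(10⁻⁶ of the data variance) also serves as the covariance
regularizer so noiseless spike distributions cannot collapse a
component. Components map to CSF < GM < WM by ascending mean.
One GM class covers cortex and deep GM; deep structures are separated
by label masks (phantom truth, or an external subcortical labeling via
a configurable code table with left/right pairs combined per
structure). Externally produced PVE maps pass through validation only.

## ROI construction

All printed constants are defaults of `RoiThresholds`: cortex PVE
≥ 0.95 with T1 ∈ [1200, 1600] ms; WM binarization at PVE ≥ 0.95 (the
0.95 is stated only for cortex in the source design; the symmetric
choice is configurable); erosion kernels 3 mm (deep GM) and 6 mm (WM)
converted per axis as round(kernel/voxel) forced odd — at 2 mm voxels
the 3 mm kernel is a single voxel (identity) and the 6 mm kernel a
3-voxel cube. The cortex exclusion mask is deep GM ∪ hole-filled WM ∪
ventricles (∪ optional cerebellum); hole-filling implements the
"filled holes" WM mask so lesions embedded in WM cannot leak into the
cortical map. The NAWM mask additionally excludes the deep-GM
structure masks before erosion: the pallidum is nearly isointense with
WM on a T1-weighted anatomy, so an intensity-only WM class absorbs it
and would bias the NAWM mean by ~0.5 %. Whole-brain masks are
parameter-specific (T1 ≤ 1600 ms for T1 statistics, PD ≤ 84.44 pu for
PD statistics) — the source design's phrasing is parallel rather than
conjunctive — with a config flag for the joint alternative. Global GM
is the voxelwise maximum of cortex weights and binary deep-GM
membership; their overlap is impossible by construction and asserted.
Every ROI excludes lesion-mask voxels. ROI means are Σwv/Σw over
fit-valid voxels; empty ROIs are flagged and excluded from statistics,
not imputed.

## Statistics

Mann–Whitney U (two-sided) uses exact enumeration for combined n ≤ 25
without ties — the study scale is n = 22 — and the tie-corrected
normal approximation otherwise. The correlation gate requires
significance *and* patient mean > control mean, matching the
directional framing of "significantly increased"; a two-sided gate and
an optional Holm correction over the group comparisons are available
but off by default (the emulated design used none). Sex enters
Spearman as a 0/1 code (rank-biserial equivalent). α ≥ 1 is treated
as the degenerate gate-everything setting (an exact U test can return
p = 1.0 exactly). The power harness replays the whole gated analysis
on truth-level cohorts (tissue scalars stand in for ROI means,
skipping image formation) and reports per-cell rejection fractions
with binomial Monte-Carlo standard errors.

## Problem sizes and determinism

The test suite and the acceptance script run everything at the
desk-scale 64³/2 mm grid: one subject simulates and maps in about one
second, the full 22-subject pipeline in well under a minute, and the
Monte-Carlo calibration uses 500 truth-level replicates per
configuration. Identical configuration + seed reproduces every TSV
byte-for-byte; the run manifest records the configuration hash and
seed.

## What passing tests do and do not show

The phantom validates the estimators, the ROI logic and the
statistical design against exact ground truth — it shows the chain is
self-consistent and correctly inverts its own forward model. It does
not exercise: real anatomy (folded cortex, thin ribbons, partial
volume at 1 mm), imperfect spoiling, relaxation effects inside B1
mapping, coarse-grid B1/T2* resampling, motion/distortion, Rician
noise at low SNR, or segmentation under real tissue heterogeneity.
Group differences and EDSS correlations in the synthetic cohort are
generated, not discovered; their recovery checks statistical
machinery, not biology.
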