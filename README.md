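# qgm — quantitative gray-matter MRI on digital phantoms

`qgm` is a tested re-implementation of a quantitative-MRI (qMRI)
gray-matter analysis for secondary progressive multiple sclerosis
(SPMS): variable-flip-angle T1 relaxometry and proton-density (PD)
mapping with B1/T2*/receive-bias corrections, synthetic MP-RAGE
anatomy generation, threshold/erosion-based ROI extraction for the
cerebral cortex, deep gray matter, normal-appearing white matter and
whole brain, and gated nonparametric group/disability statistics —
exercised end to end on a synthetic digital-phantom cohort with known
ground truth. It is aimed at methods researchers who want to validate
or stress-test this class of pipeline where every "true" tissue value
is known exactly.

## The method

**T1 mapping (VFA).** Two ideally spoiled gradient-echo volumes at flip
angles α₁/α₂ = 4°/24° (TR/TE = 16.4/6.7 ms) follow

S(α) = PD · sin(b₁α) (1 − E₁) / (1 − cos(b₁α) E₁) · e^(−TE/T2\*),  E₁ = e^(−TR/T1),

where b₁ is the local transmit-field scale. Plotting Sᵢ/tan(b₁αᵢ)
against Sᵢ/sin(b₁αᵢ) linearizes the model; with two angles the slope
E₁ (hence T1) and intercept M(1 − E₁) are closed-form per voxel.

**B1 mapping.** A magnetization-prepared volume divided by a
fully-relaxed reference gives cos(b₁·45°) per voxel;
b₁ = arccos(quotient)/45°.

**T2\* mapping.** A dual-echo pair (TE 4.3/11 ms) gives
T2\* = ΔTE / ln(S₁/S₂).

**PD mapping.** The fit amplitude is corrected for T2* decay and for
the receive-coil sensitivity profile (estimated by dividing the
corrected amplitude by the water content the Fatouros relation
1/W = A + B/T1 predicts, and fitting a smooth 3-D polynomial), then
normalized to 100 percent units (pu) at the ventricular-CSF median.

**ROIs.** A synthetic MP-RAGE (TR/TI/α = 1900 ms/900 ms/9°) computed
from the T1/PD maps is segmented into GM/WM/CSF partial-volume
estimates (PVE) by a Gaussian mixture; the cortex ROI keeps GM PVE
≥ 0.95 outside deep GM/WM/ventricles with absolute T1 in
[1200, 1600] ms, weighted by PVE; deep-GM structures (thalamus,
caudate, putamen, pallidum) are eroded with a 3×3×3 mm³ cube; NAWM is
binarized WM eroded with a 6×6×6 mm³ cube; whole-brain masks exclude
CSF at T1 > 1600 ms (or PD > 84.44 pu, the Fatouros equivalent).
Lesion-mask voxels are removed from every ROI.

**Statistics.** Per ROI and parameter, patients vs. controls are
compared with a two-sided Mann–Whitney U test (exact for the study's
sample sizes); Spearman correlations with EDSS, age, sex and disease
duration are computed *only* for cells whose group comparison is
significant (α = 0.05) with the patient mean above the control mean.

The phantom cohort (11 patients / 11 controls by default) draws
per-subject tissue T1/PD from group-specific Gaussians matching
published SPMS cohort values, and links patient gray-matter values
linearly to a truncated-Gaussian EDSS score (mean 5.8, SD 1.88, range
3–8.5), so disability correlations have a known generative truth.

## Worked example

```bash
qgm run --seed 7 --out qgm_run
# done: 16 group comparisons, 9 significant; reports in qgm_run
```

`qgm_run/table1.tsv` then contains rows such as (values in pu for PD,
ms for T1):

```
roi      parameter  patient_mean  patient_sd  control_mean  control_sd  U      p         significant
nagm     pd         83.47         2.65        79.89         2.36        103.0  0.004102  True
cortex   pd         83.70         2.87        80.55         2.43        57.0   0.046401  True
caudate  pd         81.28         2.41        81.18         2.07        63.0   0.897663  False
pallidum pd         77.84         2.22        73.93         1.44        116.0  0.000054  True
```

i.e. gray-matter PD is elevated in the simulated patient group
everywhere except the caudate (which the generator draws with nearly
identical group distributions), echoing the cohort the generator is
calibrated to. `table2.tsv` holds the gated Spearman correlations; with
the default disability link, whole-gray-matter PD correlates with EDSS
(here r = 0.84, p = 0.001) while non-gated cells emit no row at all.

Each stage is also exposed individually (`qgm simulate-cohort`,
`map-qmri`, `synthesize-anatomy`, `segment`, `extract-rois`,
`analyze`), reading and writing NIfTI-1 volumes and TSV tables.

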