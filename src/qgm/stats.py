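"""Gated nonparametric group and disability statistics.

The statistical design has two stages.  Stage one compares each ROI's
mean parameter value (T1 or PD) between patients and controls with a
two-sided Mann-Whitney U test.  Stage two — the gate — computes
Spearman rank correlations between the parameter and clinical
covariates (EDSS, age, sex, disease duration) in the patient group
*only* for ROI/parameter cells whose group comparison was significant
with the patient mean above the control mean: correlating with
disability is only meaningful where a disease effect exists at all.

No multiple-testing correction is applied by default (each test is
judged at alpha = 0.05); an optional Holm step over the group
comparisons is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "StatReport",
    "mann_whitney_u",
    "spearman_rank",
    "gated_analysis",
    "power_experiment",
]

EXACT_MWU_MAX_N = 25  # combined-sample cutoff for exact enumeration
COVARIATES = ("edss", "age", "sex", "disease_duration")


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of group_a, p).

    Uses exact enumeration when the combined sample size is at most 25
    and the data contain no ties; otherwise the normal approximation
    with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= EXACT_MWU_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def spearman_rank(x, y) -> tuple[float, float]:
    """Spearman rank correlation with the t-approximation p-value.

    Ties are handled by average ranking; a constant input vector leaves
    the coefficient undefined and returns (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must be paired")
    if x.size < 3:
        raise ValueError("need at least three pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return float("nan"), float("nan")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupComparison:
    roi: str
    parameter: str  # 't1' | 'pd'
    patient_mean: float
    patient_sd: float
    control_mean: float
    control_sd: float
    u_statistic: float
    p_value: float
    significant: bool
    n_patients: int
    n_controls: int


@dataclass
class CorrelationResult:
    roi: str
    parameter: str
    covariate: str
    tested: bool  # gate outcome
    r: float | None = None
    p_value: float | None = None


@dataclass
class StatReport:
    """Group-comparison and gated-correlation tables for one cohort."""

    comparisons: list[GroupComparison] = field(default_factory=list)
    correlations: list[CorrelationResult] = field(default_factory=list)
    alpha: float = 0.05

    def table1_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "roi": c.roi,
                    "parameter": c.parameter,
                    "patient_mean": c.patient_mean,
                    "patient_sd": c.patient_sd,
                    "control_mean": c.control_mean,
                    "control_sd": c.control_sd,
                    "U": c.u_statistic,
                    "p": c.p_value,
                    "significant": c.significant,
                }
                for c in self.comparisons
            ]
        )

    def table2_frame(self) -> pd.DataFrame:
        """Correlation rows for gated-in cells only."""
        return pd.DataFrame(
            [
                {
                    "roi": c.roi,
                    "parameter": c.parameter,
                    "covariate": c.covariate,
                    "r": c.r,
                    "p": c.p_value,
                }
                for c in self.correlations
                if c.tested
            ],
            columns=["roi", "parameter", "covariate", "r", "p"],
        )


def _holm(pvals: list[float], alpha: float) -> list[bool]:
    order = np.argsort(pvals)
    m = len(pvals)
    reject = [False] * m
    for rank, idx in enumerate(order):
        if pvals[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def gated_analysis(
    measurements: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    direction_gate: bool = True,
    holm: bool = False,
) -> StatReport:
    """Run the two-stage design on a long-format measurement table.

    ``measurements`` needs columns subject_id, roi, parameter, mean;
    ``covariates`` needs subject_id, group, edss, age, sex,
    disease_duration.  Cells gate into stage two when the group
    comparison is significant and (with ``direction_gate``, the
    default) the patient mean exceeds the control mean; stage two
    correlates the patient-group values with each clinical covariate.
    """
    cov = covariates.set_index("subject_id")
    missing = set(measurements["subject_id"]) - set(cov.index)
    if missing:
        raise ValueError(f"subjects missing from covariate table: {sorted(missing)}")

    meas = measurements.dropna(subset=["mean"])
    comparisons: list[GroupComparison] = []
    cells: list[tuple[str, str, pd.DataFrame]] = []
    for (roi, parameter), cell in meas.groupby(["roi", "parameter"], sort=False):
        groups = cov.loc[cell["subject_id"], "group"].to_numpy()
        pat = cell.loc[groups == "patient", "mean"].to_numpy()
        ctl = cell.loc[groups == "control", "mean"].to_numpy()
        if pat.size < 2 or ctl.size < 2:
            raise ValueError(f"cell {roi}/{parameter} lacks both groups")
        u, p = mann_whitney_u(pat, ctl)
        comparisons.append(
            GroupComparison(
                roi=roi,
                parameter=parameter,
                patient_mean=float(pat.mean()),
                patient_sd=float(pat.std(ddof=1)),
                control_mean=float(ctl.mean()),
                control_sd=float(ctl.std(ddof=1)),
                u_statistic=u,
                p_value=p,
                # alpha >= 1 is the degenerate gate-everything setting
                # (p can equal 1.0 exactly for a balanced exact U test)
                significant=bool(p < alpha or alpha >= 1.0),
                n_patients=int(pat.size),
                n_controls=int(ctl.size),
            )
        )
        cells.append((roi, parameter, cell.loc[groups == "patient"]))

    if holm:
        rejects = _holm([c.p_value for c in comparisons], alpha)
        for c, rej in zip(comparisons, rejects):
            c.significant = rej

    correlations: list[CorrelationResult] = []
    for comp, (roi, parameter, pat_cell) in zip(comparisons, cells):
        gated_in = comp.significant and (
            not direction_gate or comp.patient_mean > comp.control_mean
        )
        if not gated_in:
            for covariate in COVARIATES:
                correlations.append(CorrelationResult(roi, parameter, covariate, False))
            continue
        pat_cov = cov.loc[pat_cell["subject_id"]]
        values = pat_cell["mean"].to_numpy()
        for covariate in COVARIATES:
            x = pat_cov[covariate].to_numpy(dtype=float)
            r, p = spearman_rank(x, values)
            r_out = None if math.isnan(r) else r
            p_out = None if math.isnan(p) else p
            correlations.append(
                CorrelationResult(roi, parameter, covariate, True, r_out, p_out)
            )
    return StatReport(comparisons=comparisons, correlations=correlations, alpha=alpha)


# tissue scalar -> ROI naming used by the truth-level power harness
_TRUTH_ROI_TISSUE = {
    "cortex": "cortex",
    "thalamus": "thalamus",
    "caudate": "caudate",
    "putamen": "putamen",
    "pallidum": "pallidum",
    "nawm": "wm",
}


def power_experiment(
    cohort,
    n_replicates: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    rois: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Monte-Carlo rejection fractions of the group comparison per cell.

    Each replicate draws a fresh cohort at the truth level (per-subject
    tissue scalars stand in for ROI means, skipping image formation),
    runs :func:`gated_analysis`, and records which cells reject.
    Returns a frame with columns roi, parameter, rejection_fraction,
    mc_se (binomial Monte-Carlo standard error), n_replicates.
    """
    from qgm.phantom import draw_subject_parameters

    if rois is None:
        rois = tuple(_TRUTH_ROI_TISSUE)
    rng = np.random.default_rng(seed)
    counts: dict[tuple[str, str], int] = {}
    for _ in range(n_replicates):
        rows = []
        cov_rows = []
        for group in ("patient", "control"):
            for i in range(cohort.n_per_group):
                sid = f"{group}{i:03d}"
                params = draw_subject_parameters(cohort, group, rng)
                cov_rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "edss": params["edss"] if params["edss"] is not None else np.nan,
                        "age": params["age"],
                        "sex": params["sex"],
                        "disease_duration": params["disease_duration"],
                    }
                )
                for roi in rois:
                    tissue = _TRUTH_ROI_TISSUE[roi]
                    for parameter in ("t1", "pd"):
                        rows.append(
                            {
                                "subject_id": sid,
                                "roi": roi,
                                "parameter": parameter,
                                "mean": params["values"][tissue][parameter],
                            }
                        )
        report = gated_analysis(pd.DataFrame(rows), pd.DataFrame(cov_rows), alpha=alpha)
        for comp in report.comparisons:
            key = (comp.roi, comp.parameter)
            counts[key] = counts.get(key, 0) + int(comp.significant)
    out = []
    for (roi, parameter), k in counts.items():
        frac = k / n_replicates
        out.append(
            {
                "roi": roi,
                "parameter": parameter,
                "rejection_fraction": frac,
                "mc_se": math.sqrt(max(frac * (1 - frac), 1e-12) / n_replicates),
                "n_replicates": n_replicates,
            }
        )
    return pd.DataFrame(out)
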