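"""Nonparametric statistics: exact U test, Spearman, gating, power harness."""

import itertools

import numpy as np
import pandas as pd
import pytest

from qgm.phantom import CohortSpec, TissueSpec, default_tissue_table
from qgm.stats import (
    gated_analysis,
    mann_whitney_u,
    power_experiment,
    spearman_rank,
)


def brute_force_mwu_p(a, b) -> tuple[float, float]:
    """Enumerate all rank assignments; two-sided p from the U null."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1 = len(a)
    combined = np.concatenate([a, b])
    ranks = pd.Series(combined).rank().to_numpy()
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n = len(combined)
    us = []
    for idx in itertools.combinations(range(n), n1):
        r = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        us.append(r)
    us = np.asarray(us)
    mean_u = n1 * (n - n1) / 2
    p = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)
    return float(u_obs), float(min(p, 1.0))


class TestMannWhitney:
    def test_fully_separated_groups(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of the 20 orderings are as extreme

    def test_identical_samples_give_p_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.5], [1.0, 2.0, 3.5])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_label_swap_symmetry(self):
        a = [1.2, 3.4, 2.2, 5.0]
        b = [2.1, 4.4, 0.3]
        u_ab, p_ab = mann_whitney_u(a, b)
        u_ba, p_ba = mann_whitney_u(b, a)
        assert p_ab == pytest.approx(p_ba)
        assert u_ab + u_ba == len(a) * len(b)

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 2), (3, 3), (4, 3), (5, 5)])
    def test_exact_p_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(20):
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            _, p = mann_whitney_u(a, b)
            _, p_ref = brute_force_mwu_p(a, b)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([1.0], [2.0, 3.0])


class TestSpearman:
    def test_hand_computed_example(self):
        # sum of squared rank differences = 2 -> r = 1 - 12/60 = 0.8
        r, _ = spearman_rank([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_monotone_pairing_is_perfect(self):
        x = [1.0, 2.5, 3.1, 7.2, 9.9]
        y = [2.0, 4.0, 8.0, 16.0, 32.0]
        r, p = spearman_rank(x, y)
        assert r == pytest.approx(1.0)

    def test_reversal_flips_sign(self):
        r_fwd, _ = spearman_rank([1, 2, 3, 4], [1, 3, 2, 4])
        r_rev, _ = spearman_rank([1, 2, 3, 4], [4, 2, 3, 1])
        assert r_rev == pytest.approx(-r_fwd)

    def test_closed_form_on_tie_free_data(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.permutation(8).astype(float)
            y = rng.permutation(8).astype(float)
            d2 = ((pd.Series(x).rank() - pd.Series(y).rank()) ** 2).sum()
            expected = 1 - 6 * d2 / (8 * (8**2 - 1))
            r, _ = spearman_rank(x, y)
            assert r == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_undefined(self):
        r, p = spearman_rank([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r) and np.isnan(p)


def _toy_tables(effect_rois, n=8, seed=0):
    """Measurement/covariate tables with a strong patient increase in
    the listed (roi, parameter) cells and identical groups elsewhere."""
    rng = np.random.default_rng(seed)
    rows, cov = [], []
    rois = ("cortex", "caudate", "pallidum")
    for group in ("patient", "control"):
        for i in range(n):
            sid = f"{group}{i}"
            edss = float(3 + (i % 6)) if group == "patient" else np.nan
            cov.append(
                {"subject_id": sid, "group": group, "edss": edss,
                 "age": 40 + i, "sex": i % 2, "disease_duration": 10 + i}
            )
            for roi in rois:
                for parameter in ("t1", "pd"):
                    base = rng.normal(100.0, 1.0)
                    if group == "patient" and (roi, parameter) in effect_rois:
                        base += 30.0 + 2.0 * edss
                    rows.append(
                        {"subject_id": sid, "roi": roi, "parameter": parameter, "mean": base}
                    )
    return pd.DataFrame(rows), pd.DataFrame(cov)


class TestGatedAnalysis:
    def test_null_roi_emits_no_correlation_rows(self):
        meas, cov = _toy_tables({("cortex", "pd")})
        report = gated_analysis(meas, cov)
        t2 = report.table2_frame()
        assert "caudate" not in set(t2["roi"])
        assert {("cortex", "pd")} == set(zip(t2["roi"], t2["parameter"]))

    def test_gating_is_parameter_wise(self):
        meas, cov = _toy_tables({("pallidum", "pd")})
        report = gated_analysis(meas, cov)
        t2 = report.table2_frame()
        pall = t2[t2["roi"] == "pallidum"]
        assert set(pall["parameter"]) == {"pd"}

    def test_alpha_one_gates_everything_in(self):
        meas, cov = _toy_tables(set())
        report = gated_analysis(meas, cov, alpha=1.0, direction_gate=False)
        t2 = report.table2_frame()
        assert len(t2) == 3 * 2 * 4  # every roi x parameter x covariate

    def test_direction_gate_blocks_patient_decreases(self):
        meas, cov = _toy_tables(set())
        # make controls higher than patients in one cell
        sel = (meas["roi"] == "cortex") & (meas["parameter"] == "t1")
        is_control = meas["subject_id"].str.startswith("control")
        meas.loc[sel & is_control, "mean"] += 50.0
        report = gated_analysis(meas, cov)
        comp = {(c.roi, c.parameter): c for c in report.comparisons}
        assert comp[("cortex", "t1")].significant  # group difference exists
        assert ("cortex", "t1") not in set(
            zip(report.table2_frame()["roi"], report.table2_frame()["parameter"])
        )

    def test_missing_covariate_subject_is_named(self):
        meas, cov = _toy_tables(set())
        cov = cov[cov["subject_id"] != "patient0"]
        with pytest.raises(ValueError, match="patient0"):
            gated_analysis(meas, cov)

    def test_gate_soundness_over_random_tables(self):
        rng = np.random.default_rng(9)
        for trial in range(5):
            meas, cov = _toy_tables(set(), seed=trial + 100)
            report = gated_analysis(meas, cov)
            comp = {(c.roi, c.parameter): c for c in report.comparisons}
            for c in report.correlations:
                if c.tested:
                    g = comp[(c.roi, c.parameter)]
                    assert g.significant and g.patient_mean > g.control_mean


def _truth_cohort(cortex_patient=None, cortex_control=None, **kwargs) -> CohortSpec:
    """Cohort with optional cortex overrides, no disability link."""
    pat = default_tissue_table("patient")
    ctl = default_tissue_table("control")
    if cortex_patient is not None:
        pat["cortex"] = TissueSpec("cortex", 1400, 20, *cortex_patient, 66.0)
    if cortex_control is not None:
        ctl["cortex"] = TissueSpec("cortex", 1400, 20, *cortex_control, 66.0)
    return CohortSpec(
        patient_tissues=pat, control_tissues=ctl,
        link_slope_t1=0.0, link_slope_pd=0.0, **kwargs,
    )


class TestPowerExperiment:
    def test_null_rejection_near_alpha(self):
        cohort = _truth_cohort(
            cortex_patient=(80.0, 2.0), cortex_control=(80.0, 2.0)
        )
        out = power_experiment(cohort, n_replicates=200, alpha=0.05, seed=1, rois=("cortex",))
        row = out[(out.roi == "cortex") & (out.parameter == "pd")].iloc[0]
        se = max(row.mc_se, np.sqrt(0.05 * 0.95 / 200))
        assert abs(row.rejection_fraction - 0.05) <= 3 * se

    def test_strong_effect_has_high_power(self):
        cohort = _truth_cohort(
            cortex_patient=(83.6, 1.93), cortex_control=(80.7, 1.60)
        )
        out = power_experiment(cohort, n_replicates=200, alpha=0.05, seed=2, rois=("cortex",))
        row = out[(out.roi == "cortex") & (out.parameter == "pd")].iloc[0]
        assert row.rejection_fraction >= 0.85

    def test_power_does_not_decrease_with_n(self):
        cohort_11 = _truth_cohort(
            cortex_patient=(82.0, 2.0), cortex_control=(80.7, 1.60), n_per_group=11
        )
        cohort_22 = _truth_cohort(
            cortex_patient=(82.0, 2.0), cortex_control=(80.7, 1.60), n_per_group=22
        )
        p11 = power_experiment(cohort_11, 150, seed=3, rois=("cortex",))
        p22 = power_experiment(cohort_22, 150, seed=3, rois=("cortex",))
        f11 = p11[(p11.parameter == "pd")].rejection_fraction.iloc[0]
        f22 = p22[(p22.parameter == "pd")].rejection_fraction.iloc[0]
        se = np.sqrt(max(f11 * (1 - f11), 0.05) / 150)
        assert f22 >= f11 - 2 * se


class TestLinkedCorrelation:
    def test_median_cortex_edss_correlation_positive_and_slope_monotone(self):
        rng_seed = 5
        medians = []
        for slope in (5.0, 14.0):
            cohort = CohortSpec(link_slope_t1=slope, link_slope_pd=0.0, seed=rng_seed)
            rs = []
            rng = np.random.default_rng(rng_seed)
            from qgm.phantom import draw_subject_parameters

            for _ in range(60):
                edss, t1 = [], []
                for _i in range(cohort.n_per_group):
                    p = draw_subject_parameters(cohort, "patient", rng)
                    edss.append(p["edss"])
                    t1.append(p["values"]["cortex"]["t1"])
                r, _ = spearman_rank(edss, t1)
                if not np.isnan(r):
                    rs.append(r)
            medians.append(np.median(rs))
        assert medians[0] > 0
        assert medians[1] > medians[0]
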