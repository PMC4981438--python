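"""Map estimation: B1, T2*, VFA T1, Fatouros relation, bias fields, PD."""

import numpy as np
import pytest

from qgm.acquisition import spgr_signal
from qgm.phantom import TISSUE_LABELS
from qgm.relaxometry import (
    FatourosCalibration,
    SpoilingCorrection,
    apply_spoiling_correction,
    compute_b1_map,
    compute_t2star_map,
    csf_pd_threshold,
    derive_pd_map,
    estimate_receive_bias,
    fatouros_water_content,
    fit_t1_vfa,
)


class TestB1Map:
    def test_cos_of_nominal_gives_unit_b1(self):
        ref = np.full((4, 4, 4), 100.0)
        prep = ref * np.cos(np.deg2rad(45.0))
        b1, valid = compute_b1_map(ref, prep, 45.0)
        assert valid.all()
        assert np.allclose(b1, 1.0)

    def test_scaled_angle_recovers_b1(self):
        ref = np.full((4, 4, 4), 100.0)
        prep = ref * np.cos(np.deg2rad(40.5))
        b1, _ = compute_b1_map(ref, prep, 45.0)
        assert np.allclose(b1, 0.9)

    def test_noise_ratio_above_one_clamps_to_zero(self):
        ref = np.full((2, 2, 2), 100.0)
        prep = ref * 1.05
        b1, valid = compute_b1_map(ref, prep, 45.0)
        assert np.allclose(b1, 0.0)  # outside any plausibility window
        assert valid.all()  # flagged downstream by the window, not here

    def test_low_reference_signal_is_invalid(self):
        ref = np.full((2, 2, 2), 100.0)
        ref[0, 0, 0] = 0.0
        b1, valid = compute_b1_map(ref, ref * 0.7, 45.0)
        assert not valid[0, 0, 0]
        assert valid.ravel()[1:].all()

    def test_zero_nominal_angle_is_a_config_error(self):
        ref = np.full((2, 2, 2), 1.0)
        with pytest.raises(ValueError):
            compute_b1_map(ref, ref, 0.0)


class TestT2StarMap:
    def test_recovers_fifty_ms(self):
        s1 = np.full((3, 3, 3), 100.0)
        s2 = s1 * np.exp(-6.7 / 50.0)
        t2s, valid = compute_t2star_map(s1, s2, 4.3, 11.0)
        assert valid.all()
        assert np.allclose(t2s, 50.0)

    def test_equal_signals_give_infinite_t2star(self):
        s = np.full((2, 2, 2), 100.0)
        t2s, valid = compute_t2star_map(s, s.copy(), 4.3, 11.0)
        assert valid.all()
        assert np.all(np.isposinf(t2s))
        # the TE correction factor exp(te/t2*) degrades gracefully to 1
        assert np.allclose(np.exp(6.7 / t2s), 1.0)

    def test_growing_signal_is_unphysical(self):
        s1 = np.full((2, 2, 2), 100.0)
        t2s, valid = compute_t2star_map(s1, s1 * 1.1, 4.3, 11.0)
        assert not valid.any()


class TestVfaFit:
    @staticmethod
    def _simulate(t1, b1, pd=80.0, t2s=66.0, tr=16.4, te=6.7):
        shape = np.broadcast(np.asarray(t1), np.asarray(b1)).shape or (1,)
        t1 = np.broadcast_to(np.asarray(t1, float), shape)
        b1a = np.broadcast_to(np.asarray(b1, float), shape)
        pd = np.full(shape, pd)
        t2s = np.full(shape, t2s)
        s1 = spgr_signal(pd, t1, t2s, 4.0, b1a, tr, te)
        s2 = spgr_signal(pd, t1, t2s, 24.0, b1a, tr, te)
        return s1, s2

    def test_round_trip_is_numerically_exact(self):
        s1, s2 = self._simulate(np.full((4, 4), 1400.0), 1.0)
        t1, m0, valid = fit_t1_vfa(s1, s2, 4.0, 24.0, np.ones((4, 4)), 16.4)
        assert valid.all()
        assert np.allclose(t1, 1400.0, rtol=1e-9)

    def test_round_trip_exact_with_matching_b1(self):
        s1, s2 = self._simulate(np.full((4, 4), 1400.0), 0.8)
        t1, _, valid = fit_t1_vfa(s1, s2, 4.0, 24.0, np.full((4, 4), 0.8), 16.4)
        assert valid.all()
        assert np.allclose(t1, 1400.0, rtol=1e-9)

    def test_overestimated_b1_shortens_apparent_t1(self):
        """Assuming B1=1 for signals generated at B1=0.8 biases T1 downward
        (approximately by the squared flip-angle ratio), verified by
        brute-force simulation."""
        s1, s2 = self._simulate(np.full((2, 2), 1400.0), 0.8)
        t1_wrong, _, valid = fit_t1_vfa(s1, s2, 4.0, 24.0, np.ones((2, 2)), 16.4)
        assert valid.all()
        assert np.all(t1_wrong < 1400.0)
        assert t1_wrong[0, 0] == pytest.approx(1400.0 * 0.8**2, rel=0.05)

    def test_unphysical_slope_flagged_not_crashed(self):
        s1 = np.full((2, 2), 10.0)
        s2 = np.full((2, 2), 10.0)  # equal signals -> slope 1 boundary
        _, _, valid = fit_t1_vfa(s1, s2, 4.0, 24.0, np.ones((2, 2)), 16.4)
        assert not valid.all() or valid.all()  # must simply not raise
        s2_big = s1 * 50.0  # slope far above 1
        _, _, valid2 = fit_t1_vfa(s1, s2_big, 4.0, 24.0, np.ones((2, 2)), 16.4)
        assert not valid2.any()

    def test_amplitude_recovers_te_decayed_pd(self):
        s1, s2 = self._simulate(np.full((3, 3), 1000.0), 1.0, pd=70.0, t2s=50.0)
        _, m0, valid = fit_t1_vfa(s1, s2, 4.0, 24.0, np.ones((3, 3)), 16.4)
        assert valid.all()
        assert np.allclose(m0, 70.0 * np.exp(-6.7 / 50.0), rtol=1e-9)


class TestSpoilingCorrection:
    def test_identity_leaves_t1_unchanged(self):
        t1 = np.array([800.0, 1400.0])
        out = apply_spoiling_correction(t1, np.ones(2), SpoilingCorrection())
        assert np.array_equal(out, t1)

    def test_scale_correction(self):
        t1 = np.array([1000.0])
        out = apply_spoiling_correction(t1, np.ones(1), SpoilingCorrection.from_scale(0.95))
        assert out[0] == pytest.approx(950.0)

    def test_serialization_round_trip(self):
        corr = SpoilingCorrection({(1, 0): 0.97, (1, 1): 0.02, (0, 0): 3.0})
        assert SpoilingCorrection.from_dict(corr.to_dict()) == corr


class TestFatouros:
    def test_default_calibration_hits_the_csf_cutoff_pair(self):
        assert fatouros_water_content(1600.0) == pytest.approx(84.44, abs=1e-9)
        assert csf_pd_threshold() == pytest.approx(84.44, abs=1e-9)

    def test_csf_anchor_is_exactly_100(self):
        cal = FatourosCalibration()
        assert fatouros_water_content(cal.t1_csf_anchor, cal) == pytest.approx(100.0)

    def test_from_anchors_reproduces_defaults(self):
        cal = FatourosCalibration.from_anchors()
        default = FatourosCalibration()
        assert cal.a == pytest.approx(default.a, rel=1e-12)
        assert cal.b == pytest.approx(default.b, rel=1e-12)

    def test_strictly_increasing_over_plausible_t1(self):
        t1 = np.linspace(500.0, 5000.0, 1000)
        w = fatouros_water_content(t1)
        assert np.all(np.diff(w) > 0)

    def test_nonpositive_t1_is_a_domain_error(self):
        with pytest.raises(ValueError):
            fatouros_water_content(0.0)


class TestReceiveBias:
    def test_flat_field_recovered_within_one_percent(self, control_subject):
        brain = control_subject.labels > 0
        wm = control_subject.labels == TISSUE_LABELS["wm"]
        amp = control_subject.true_pd.astype(float)  # receive field == 1
        field = estimate_receive_bias(amp, control_subject.true_t1, brain, fit_mask=wm)
        # flat up to one global tissue scale
        assert (field[brain].max() - field[brain].min()) / field[brain].mean() < 0.01

    def test_polynomial_field_recovered_in_brain(self, control_subject):
        from qgm.acquisition import polynomial_field

        brain = control_subject.labels > 0
        truth_field = polynomial_field(
            control_subject.labels.shape, {(2, 0, 0): -0.1, (0, 1, 0): 0.08}, offset=1.0
        )
        wm = control_subject.labels == TISSUE_LABELS["wm"]
        amp = control_subject.true_pd * truth_field
        est = estimate_receive_bias(amp, control_subject.true_t1, brain, fit_mask=wm)
        ratio = est[brain] / truth_field[brain]
        # recovered up to one global scale
        assert (ratio.max() - ratio.min()) / ratio.mean() < 0.02

    def test_oracle_mode_passes_field_through(self, control_subject):
        known = np.full(control_subject.labels.shape, 1.23)
        out = estimate_receive_bias(
            known * 0.0, control_subject.true_t1, control_subject.labels > 0, known_field=known
        )
        assert np.array_equal(out, known)

    def test_too_few_voxels_raises(self):
        amp = np.ones((6, 6, 6))
        t1 = np.full((6, 6, 6), 900.0)
        mask = np.zeros((6, 6, 6), bool)
        mask[0, 0, :3] = True
        with pytest.raises(ValueError, match="too few"):
            estimate_receive_bias(amp, t1, mask)


class TestPdMap:
    def test_csf_median_is_exactly_100(self, mapped_subject, oracle_maps):
        csf = mapped_subject.labels == TISSUE_LABELS["csf"]
        assert np.median(oracle_maps.pd[csf]) == pytest.approx(100.0, abs=1e-9)

    def test_wm_pd_recovered_within_half_percent(self, mapped_subject, oracle_maps):
        wm = mapped_subject.labels == TISSUE_LABELS["wm"]
        truth = mapped_subject.tissue_values["wm"]["pd"]
        assert oracle_maps.pd[wm].mean() == pytest.approx(truth, rel=0.005)

    def test_global_receive_scale_cancels(self):
        m0 = np.full((4, 4, 4), 50.0)
        t2s = np.full((4, 4, 4), 60.0)
        csf = np.zeros((4, 4, 4), bool)
        csf[0] = True
        m0[0] = 80.0
        pd_a = derive_pd_map(m0, t2s, np.ones_like(m0), 6.7, csf)
        pd_b = derive_pd_map(m0, t2s, np.full_like(m0, 0.5), 6.7, csf)
        assert np.allclose(pd_a, pd_b)

    def test_empty_csf_mask_raises(self):
        m0 = np.ones((2, 2, 2))
        with pytest.raises(ValueError, match="CSF"):
            derive_pd_map(m0, m0, m0, 6.7, np.zeros((2, 2, 2), bool))


class TestFullRoundTrip:
    def test_oracle_bias_round_trip_below_1e6(self, mapped_subject, oracle_maps, bias_fields):
        ok = oracle_maps.valid_mask
        brain = mapped_subject.labels > 0
        assert (ok & brain).sum() == brain.sum()
        for est, truth in (
            (oracle_maps.t1, mapped_subject.true_t1),
            (oracle_maps.pd, mapped_subject.true_pd),
            (oracle_maps.b1, bias_fields.b1_field),
            (oracle_maps.t2star, mapped_subject.true_t2star),
        ):
            rel = np.abs(est[brain] - truth[brain]) / truth[brain]
            assert rel.max() < 1e-6

    def test_estimated_bias_roi_means_below_one_percent(self, mapped_subject, estimated_maps):
        for name, code in TISSUE_LABELS.items():
            m = (mapped_subject.labels == code) & estimated_maps.valid_mask
            assert m.any(), name
            truth = mapped_subject.tissue_values[name]
            assert estimated_maps.t1[m].mean() == pytest.approx(truth["t1"], rel=0.01)
            assert estimated_maps.pd[m].mean() == pytest.approx(truth["pd"], rel=0.01)

    def test_b1_map_ignores_receive_field_and_pd(self, mapped_subject, oracle_maps, bias_fields):
        # the quotient construction cancels both multiplicative factors
        brain = mapped_subject.labels > 0
        assert np.allclose(oracle_maps.b1[brain], bias_fields.b1_field[brain], rtol=1e-9)
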