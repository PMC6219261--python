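import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patlak_gfr.calibration import concentration_to_si
from patlak_gfr.errors import (
    AlreadySubtractedWarning,
    CalibrationRangeWarning,
    GridMismatchError,
    NegativeValueWarning,
)
from patlak_gfr.preprocessing import (
    ConcentrationCurve,
    DynamicSeries,
    RoiSet,
    SignalCurve,
    Subject,
    TissueGeometry,
    body_surface_area,
    contrast_volume_per_kg,
    correct_residual_tissue,
    curve_to_concentration,
    extract_roi_mean,
    smooth_curve,
    smoothing_window_span,
    subtract_baseline,
)


def _series(frames):
    return DynamicSeries(frames=np.asarray(frames, dtype=float))


def _times(n, dt=0.58):
    return np.arange(n) * dt


class TestDynamicSeries:
    def test_requires_20_frames(self):
        with pytest.raises(ValueError):
            DynamicSeries(frames=np.zeros((10, 4, 4)))

    def test_times_grid(self):
        s = _series(np.zeros((25, 2, 2)))
        assert s.times[1] - s.times[0] == pytest.approx(0.58)
        assert len(s.times) == 25


class TestSubtractBaseline:
    def test_self_subtraction_gives_zero(self):
        frames = np.tile(np.arange(16.0).reshape(4, 4), (24, 1, 1))
        out = subtract_baseline(_series(frames))
        assert np.all(out.frames == 0)

    def test_recovers_known_enhancement(self):
        rng = np.random.default_rng(0)
        baseline = rng.uniform(50, 150, size=(4, 4))
        enhancement = rng.uniform(0, 30, size=(24, 4, 4))
        enhancement[:3] = 0.0  # frames up to the reference carry no signal
        out = subtract_baseline(_series(baseline + enhancement))
        np.testing.assert_allclose(out.frames, enhancement, atol=1e-12)

    def test_idempotent_with_warning(self):
        s = _series(np.random.default_rng(1).uniform(size=(24, 3, 3)))
        once = subtract_baseline(s)
        with pytest.warns(AlreadySubtractedWarning):
            twice = subtract_baseline(once)
        np.testing.assert_array_equal(once.frames, twice.frames)

    def test_frames_up_to_baseline_zeroed(self):
        s = _series(np.random.default_rng(2).uniform(1, 2, size=(24, 3, 3)))
        out = subtract_baseline(s)
        assert np.all(out.frames[:3] == 0)


class TestExtractRoiMean:
    def test_single_voxel_mask(self):
        frames = np.random.default_rng(3).uniform(size=(25, 4, 4))
        mask = np.zeros((4, 4), dtype=bool)
        mask[2, 1] = True
        curve = extract_roi_mean(_series(frames), mask)
        np.testing.assert_allclose(curve.values, frames[:, 2, 1])

    def test_antisymmetric_traces_cancel(self):
        f = np.sin(np.linspace(0, 6, 24))
        frames = np.zeros((24, 2, 2))
        frames[:, 0, 0] = f
        frames[:, 0, 1] = -f
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, :] = True
        curve = extract_roi_mean(_series(frames), mask)
        np.testing.assert_allclose(curve.values, 0.0, atol=1e-15)

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(4)
        frames = rng.uniform(size=(30, 5, 6))
        mask = rng.uniform(size=(5, 6)) > 0.5
        curve = extract_roi_mean(_series(frames), mask)
        expected = [frames[t][mask].mean() for t in range(30)]  # brute-force oracle
        np.testing.assert_allclose(curve.values, expected)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_roi_mean(_series(np.zeros((24, 2, 2))), np.zeros((2, 2), bool))

    def test_linear_in_series(self):
        rng = np.random.default_rng(5)
        f1, f2 = rng.uniform(size=(2, 24, 3, 3))
        mask = np.ones((3, 3), bool)
        c1 = extract_roi_mean(_series(f1), mask).values
        c2 = extract_roi_mean(_series(f2), mask).values
        c12 = extract_roi_mean(_series(2 * f1 + 3 * f2), mask).values
        np.testing.assert_allclose(c12, 2 * c1 + 3 * c2, atol=1e-12)


class TestSmoothCurve:
    def test_polynomial_reproduced_exactly(self):
        t = _times(60)
        values = 1.5 + 0.3 * t - 0.02 * t**2
        sm = smooth_curve(SignalCurve(t, values))
        np.testing.assert_allclose(sm.values[7:-7], values[7:-7], atol=1e-9)

    def test_constant_curve_unchanged(self):
        t = _times(40)
        sm = smooth_curve(SignalCurve(t, np.full(40, 5.0)))
        np.testing.assert_allclose(sm.values, 5.0, atol=1e-12)

    def test_high_frequency_variance_reduced(self):
        t = _times(200)
        trend = 0.5 * t
        noise = np.sin(2 * np.pi * t / (3 * 0.58))  # period of 3 frames
        sm = smooth_curve(SignalCurve(t, trend + noise))
        residual_in = noise[10:-10]
        residual_out = (sm.values - trend)[10:-10]
        assert np.var(residual_out) <= 0.2 * np.var(residual_in)

    def test_length_and_grid_preserved(self):
        t = _times(50)
        sm = smooth_curve(SignalCurve(t, np.random.default_rng(0).uniform(size=50)))
        assert len(sm) == 50
        np.testing.assert_array_equal(sm.times, t)
        assert sm.smoothed

    @pytest.mark.parametrize("window", [14, 61])
    def test_invalid_window_rejected(self, window):
        curve = SignalCurve(_times(40), np.zeros(40))
        with pytest.raises(ValueError):
            smooth_curve(curve, window_frames=window)

    def test_window_below_order_rejected(self):
        curve = SignalCurve(_times(40), np.zeros(40))
        with pytest.raises(ValueError):
            smooth_curve(curve, window_frames=3, poly_order=2)


class TestCurveToConcentration:
    def test_zero_si_gives_offset(self, model):
        curve = SignalCurve(_times(30), np.zeros(30))
        conc = curve_to_concentration(curve, model)
        np.testing.assert_allclose(conc.values, 0.063, atol=1e-12)

    def test_inverts_forward_rendering(self, model):
        t = _times(40)
        truth = np.linspace(0.5, 12.0, 40)
        si = concentration_to_si(truth, model)
        conc = curve_to_concentration(SignalCurve(t, si), model)
        np.testing.assert_allclose(conc.values, truth, atol=1e-9)

    def test_out_of_range_peak_warns(self, model):
        values = np.zeros(30)
        values[15] = 1250.0
        with pytest.warns(CalibrationRangeWarning):
            curve_to_concentration(SignalCurve(_times(30), values), model)

    def test_negative_si_clipped_with_warning(self, model):
        values = np.full(30, -5.0)
        with pytest.warns(NegativeValueWarning):
            conc = curve_to_concentration(SignalCurve(_times(30), values), model)
        np.testing.assert_allclose(conc.values, 0.063, atol=1e-12)

    def test_zero_offset_subtraction_option(self, model):
        curve = SignalCurve(_times(30), np.zeros(30))
        conc = curve_to_concentration(curve, model, subtract_zero_offset=True)
        np.testing.assert_allclose(conc.values, 0.0, atol=1e-12)


class TestCorrectResidualTissue:
    def test_no_residual_is_identity(self):
        t = _times(25)
        organ = ConcentrationCurve(t, np.linspace(1, 5, 25))
        corr = ConcentrationCurve(t, np.linspace(0, 1, 25))
        geom = TissueGeometry(v_voxel=10.0, v_tissue=10.0)
        out = correct_residual_tissue(organ, corr, geom)
        np.testing.assert_allclose(out.values, organ.values)

    def test_hand_worked_example(self):
        # c_voxel=2, c_res=1, V_voxel=10, V_tissue=5, V_res=5 -> 2*2 - 1*1 = 3
        t = _times(25)
        out = correct_residual_tissue(
            ConcentrationCurve(t, np.full(25, 2.0)),
            ConcentrationCurve(t, np.full(25, 1.0)),
            TissueGeometry(v_voxel=10.0, v_tissue=5.0),
        )
        np.testing.assert_allclose(out.values, 3.0)

    def test_inverts_voxel_mixing(self):
        rng = np.random.default_rng(6)
        t = _times(30)
        c_true = rng.uniform(1, 10, size=30)
        c_res = rng.uniform(0, 2, size=30)
        geom = TissueGeometry(v_voxel=12.0, v_tissue=7.0)
        c_voxel = (c_true * geom.v_tissue + c_res * geom.v_residual) / geom.v_voxel
        out = correct_residual_tissue(
            ConcentrationCurve(t, c_voxel), ConcentrationCurve(t, c_res), geom
        )
        np.testing.assert_allclose(out.values, c_true, atol=1e-9)

    def test_negative_result_retained_with_warning(self):
        t = _times(25)
        with pytest.warns(NegativeValueWarning):
            out = correct_residual_tissue(
                ConcentrationCurve(t, np.full(25, 0.1)),
                ConcentrationCurve(t, np.full(25, 5.0)),
                TissueGeometry(v_voxel=10.0, v_tissue=5.0),
            )
        assert np.all(out.values < 0)

    def test_grid_mismatch_rejected(self):
        organ = ConcentrationCurve(_times(25), np.ones(25))
        corr = ConcentrationCurve(_times(25, dt=0.5), np.ones(25))
        with pytest.raises(GridMismatchError):
            correct_residual_tissue(organ, corr, TissueGeometry(10.0, 5.0))

    @settings(max_examples=50, deadline=None)
    @given(
        v_voxel=st.floats(1.0, 100.0),
        tissue_frac=st.floats(0.05, 1.0),
        seed=st.integers(0, 1000),
    )
    def test_mixing_round_trip_any_geometry(self, v_voxel, tissue_frac, seed):
        rng = np.random.default_rng(seed)
        t = _times(25)
        geom = TissueGeometry(v_voxel=v_voxel, v_tissue=tissue_frac * v_voxel)
        c_true = rng.uniform(0, 20, size=25)
        c_res = rng.uniform(0, 5, size=25)
        c_voxel = (c_true * geom.v_tissue + c_res * geom.v_residual) / geom.v_voxel
        out = correct_residual_tissue(
            ConcentrationCurve(t, c_voxel), ConcentrationCurve(t, c_res), geom
        )
        np.testing.assert_allclose(out.values, c_true, atol=1e-8 * max(1.0, v_voxel / geom.v_tissue))


class TestTissueGeometry:
    def test_residual_is_exact_difference(self):
        geom = TissueGeometry(v_voxel=10.0, v_tissue=7.5)
        assert geom.v_residual == 10.0 - 7.5

    def test_invalid_volumes_rejected(self):
        with pytest.raises(ValueError):
            TissueGeometry(v_voxel=0.0, v_tissue=0.0)
        with pytest.raises(ValueError):
            TissueGeometry(v_voxel=5.0, v_tissue=6.0)


class TestSubject:
    def test_body_surface_derived_from_weight(self):
        subject = Subject(body_weight=17.5)
        assert subject.body_surface == pytest.approx(0.6746932705316802)

    def test_hematocrit_default(self):
        assert Subject().hematocrit == 0.47

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            Subject(body_weight=-1.0)
        with pytest.raises(ValueError):
            Subject(hematocrit=1.5)


class TestScalarHelpers:
    def test_body_surface_unit_weight(self):
        assert body_surface_area(1.0) == pytest.approx(0.1)

    def test_body_surface_14_kg(self):
        assert body_surface_area(14.0) == pytest.approx(0.581389788796757)

    def test_body_surface_22_kg(self):
        assert body_surface_area(22.0) == pytest.approx(0.7859518274960837)

    def test_body_surface_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            body_surface_area(0.0)

    def test_contrast_volume_per_kg(self):
        assert contrast_volume_per_kg(0.1, 0.5) == pytest.approx(0.2)

    def test_smoothing_window_span(self):
        assert smoothing_window_span(15, 0.58) == pytest.approx(8.7)


class TestFullChain:
    def test_reconstructs_truth_in_evaluation_window(self, noiseless_subject, noiseless_result):
        """Chain output matches the smoothed generator curves where the fit reads them."""
        from patlak_gfr.patlak import PipelineConfig, _smoothed_concentration

        cfg = PipelineConfig()
        lm = noiseless_result.landmarks_left
        window = (lm.t_aorta_max2, lm.t_aorta_max2 + 60.0)
        for label, corr_label in (
            ("aorta_all", "correction_aorta"),
            ("kidney_left", "correction_left"),
            ("kidney_right", "correction_right"),
        ):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                conc = _smoothed_concentration(
                    noiseless_subject.si_curves[label], noiseless_subject.calibration, cfg
                )
                corr = _smoothed_concentration(
                    noiseless_subject.si_curves[corr_label], noiseless_subject.calibration, cfg
                )
                rec = correct_residual_tissue(conc, corr, noiseless_subject.geometry[label])
                truth_sm = smooth_curve(noiseless_subject.conc_truth[label], 15, 2)
            sel = (rec.times >= window[0]) & (rec.times <= window[1])
            np.testing.assert_allclose(
                rec.values[sel], truth_sm.values[sel], rtol=5e-3
            )
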