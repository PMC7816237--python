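import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fairmbf import (ImageFrame, PhantomSpec, RigidTransform, average_series,
                     correct_inversion_time, crop_roi, forward_signals,
                     get_protocol, make_geometry, mbf_map, preprocess_series,
                     register_rigid, simulate_series)
from fairmbf._imageops import apply_rigid


class TestCropRoi:
    def test_full_grid_window_is_identity(self, clean_series):
        series, _ = clean_series
        out = crop_roi(series, size_px=150)
        np.testing.assert_array_equal(out.m0.pixels, series.m0.pixels)

    def test_centered_window_index_arithmetic(self, clean_series):
        series, _ = clean_series
        out = crop_roi(series, size_px=64)
        assert out.m0.shape == (64, 64)
        # pixel (0,0) of the crop maps from source pixel (43,43)
        assert out.m0.pixels[0, 0] == series.m0.pixels[43, 43]

    def test_window_outside_grid_rejected(self, clean_series):
        series, _ = clean_series
        with pytest.raises(ValueError, match="exceeds"):
            crop_roi(series, center_px=(10, 10), size_px=64)

    def test_window_applied_identically_to_all_frames(self, clean_series):
        series, _ = clean_series
        out = crop_roi(series, size_px=64)
        assert len(out.frames()) == 13
        for src, dst in zip(series.frames(), out.frames()):
            np.testing.assert_array_equal(dst.pixels, src.pixels[43:107, 43:107])
            assert dst.actual_ti_ms == src.actual_ti_ms


class TestRegisterRigid:
    @pytest.fixture
    def asym_control(self, asym_spec, diastole_protocol, crop_slices):
        c, _, _ = forward_signals(asym_spec, diastole_protocol)
        return ImageFrame(c.pixels[crop_slices], "control", 1, 1000.0)

    def test_self_registration_is_identity(self, asym_control):
        res = register_rigid(asym_control, asym_control)
        assert res.transform.is_near_identity(0.1, 0.1)
        np.testing.assert_allclose(res.aligned.pixels, asym_control.pixels,
                                   atol=1e-6)

    @pytest.mark.parametrize("metric", ["mean_squares", "mutual_information"])
    @pytest.mark.parametrize("inj", [
        RigidTransform(3.0, -2.0, 0.0),
        RigidTransform(0.0, 0.0, 5.0),
        RigidTransform(-2.0, 1.5, 3.0),
    ])
    def test_injected_transform_recovered(self, asym_control, metric, inj):
        moved = apply_rigid(asym_control.pixels, inj, (2.0, 2.0), (31.5, 31.5),
                            fill=asym_control.pixels[0, 0])
        res = register_rigid(ImageFrame(moved, "control", 2, 1000.0),
                             asym_control, metric=metric)
        expected = inj.inverse()
        assert res.transform.tx_px == pytest.approx(expected.tx_px, abs=0.5)
        assert res.transform.ty_px == pytest.approx(expected.ty_px, abs=0.5)
        assert res.transform.theta_deg == pytest.approx(expected.theta_deg, abs=0.5)

    def test_mismatched_grids_rejected(self, asym_control):
        other = ImageFrame(np.zeros((32, 32)), "control", 1, 1000.0)
        with pytest.raises(ValueError, match="grids differ"):
            register_rigid(other, asym_control)

    def test_unknown_metric_rejected(self, asym_control):
        with pytest.raises(ValueError, match="metric"):
            register_rigid(asym_control, asym_control, metric="ncc")


class TestInversionTimeCorrection:
    def test_zero_delta_is_identity(self):
        fr = ImageFrame(np.array([[400.0, 700.0]]), "control", 1, 1000.0)
        m0 = ImageFrame(np.array([[1000.0, 1000.0]]), "m0")
        out = correct_inversion_time(fr, m0, 1000.0, 1700.0)
        np.testing.assert_array_equal(out.pixels, fr.pixels)
        assert out.actual_ti_ms == 1000.0

    def test_signal_at_equilibrium_stays_at_equilibrium(self):
        fr = ImageFrame(np.full((2, 2), 1000.0), "tagged", 1, 1250.0)
        m0 = ImageFrame(np.full((2, 2), 1000.0), "m0")
        out = correct_inversion_time(fr, m0, 1000.0, 1700.0)
        np.testing.assert_allclose(out.pixels, 1000.0, rtol=1e-14)

    def test_scalar_oracle_value(self):
        # 1000 - 600 e^(100/1700) = 363.647..., hand-evaluated
        fr = ImageFrame(np.array([[400.0]]), "control", 1, 1100.0)
        m0 = ImageFrame(np.array([[1000.0]]), "m0")
        out = correct_inversion_time(fr, m0, 1000.0, 1700.0)
        assert out.pixels[0, 0] == pytest.approx(363.6471630245619, abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(signal=st.floats(-2000, 2000), m0val=st.floats(10, 2000),
           dti=st.floats(-200, 200))
    def test_round_trip_inverts_to_machine_precision(self, signal, m0val, dti):
        fr = ImageFrame(np.array([[signal]]), "control", 1, 1000.0 + dti)
        m0 = ImageFrame(np.array([[m0val]]), "m0")
        fwd = correct_inversion_time(fr, m0, 1000.0, 1700.0)
        back = correct_inversion_time(
            ImageFrame(fwd.pixels, "control", 1, 1000.0), m0,
            1000.0 + dti, 1700.0)
        assert back.pixels[0, 0] == pytest.approx(signal, rel=1e-12, abs=1e-9)

    def test_nonpositive_t1_rejected(self):
        fr = ImageFrame(np.zeros((2, 2)), "control", 1, 1000.0)
        m0 = ImageFrame(np.zeros((2, 2)), "m0")
        with pytest.raises(ValueError):
            correct_inversion_time(fr, m0, 1000.0, 0.0)


class TestAverageSeries:
    def test_identical_frames_average_to_themselves(self):
        frames = [ImageFrame(np.full((3, 3), 7.0), "control", i + 1, 1000.0)
                  for i in range(6)]
        avg, ti = average_series(frames)
        np.testing.assert_array_equal(avg.pixels, 7.0 * np.ones((3, 3)))
        assert ti == 1000.0

    def test_pixelwise_arithmetic_mean_and_mean_ti(self):
        frames = [ImageFrame(np.array([[float(v)]]), "tagged", v, ti)
                  for v, ti in zip(range(1, 7), (990, 1010, 1000, 1000, 995, 1005))]
        avg, ti = average_series(frames)
        assert avg.pixels[0, 0] == pytest.approx(3.5)
        assert ti == pytest.approx(1000.0)

    def test_two_frame_series_ti(self):
        frames = [ImageFrame(np.zeros((1, 1)), "control", i + 1, ti)
                  for i, ti in enumerate((990.0, 1010.0))]
        _, ti = average_series(frames)
        assert ti == pytest.approx(1000.0)

    def test_empty_and_mixed_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            average_series([])
        mixed = [ImageFrame(np.zeros((1, 1)), "control", 1, 1000.0),
                 ImageFrame(np.zeros((1, 1)), "tagged", 1, 1000.0)]
        with pytest.raises(ValueError, match="mixed"):
            average_series(mixed)


class TestPreprocessSeries:
    def test_zero_corruption_yields_noiseless_pair(self, clean_spec,
                                                   diastole_protocol, crop_slices):
        series, truth = simulate_series(clean_spec, diastole_protocol)
        pair = preprocess_series(series)
        c, t, _ = forward_signals(clean_spec, diastole_protocol)
        np.testing.assert_allclose(pair.control_avg.pixels, c.pixels[crop_slices],
                                   rtol=1e-12, atol=1e-9)
        np.testing.assert_allclose(pair.tagged_avg.pixels, t.pixels[crop_slices],
                                   rtol=1e-12, atol=1e-9)
        for key in ("control", "tagged", "to_m0"):
            for tx in pair.transform_log[key]:
                assert tx.is_near_identity(0.1, 0.1)

    def test_injected_pair_shifts_recovered_in_transform_log(self, asym_spec,
                                                             diastole_protocol):
        spec = replace(asym_spec, motion_shift_px=3.0, motion_rot_deg=3.0, seed=3)
        series, truth = simulate_series(spec, diastole_protocol)
        pair = preprocess_series(series)
        inj = truth.injected_transforms[:6]
        for i in range(1, 6):
            # frames are registered to frame 1, so the expected correction is
            # inj_i^{-1} composed with inj_1
            exp = inj[i].inverse().compose(inj[0])
            got = pair.transform_log["control"][i]
            assert got.tx_px == pytest.approx(exp.tx_px, abs=0.5)
            assert got.ty_px == pytest.approx(exp.ty_px, abs=0.5)
            assert got.theta_deg == pytest.approx(exp.theta_deg, abs=0.5)

    def test_ti_jitter_alone_is_fully_corrected(self, clean_spec,
                                                diastole_protocol, crop_slices):
        spec = replace(clean_spec, ti_jitter_frac=0.05, seed=11)
        series, truth = simulate_series(spec, diastole_protocol)
        pair = preprocess_series(series)
        myo = truth.myo_mask[crop_slices]
        out = mbf_map(pair.control_avg, pair.tagged_avg, pair.m0,
                      pair.ti_control_ms, pair.ti_tagged_ms,
                      series.blood_t1_ms, myo_mask=myo)
        np.testing.assert_allclose(out.values[out.analysis_mask], 1.5, rtol=1e-6)

    def test_correcting_before_averaging_matters(self, clean_spec,
                                                 diastole_protocol):
        # averaging jittered frames without TI correction gives a different
        # (wrong) result: guards the pipeline stage order
        spec = replace(clean_spec, ti_jitter_frac=0.05, seed=13)
        series, _ = simulate_series(spec, diastole_protocol)
        pair = preprocess_series(series)
        # the swap error is second order in the TI jitter, so small but far
        # above floating-point noise
        raw_mean = np.mean([f.pixels[43:107, 43:107] for f in series.taggeds],
                           axis=0)
        assert np.max(np.abs(raw_mean - pair.tagged_avg.pixels)) > 0.05

    def test_registration_lowers_mbf_error_on_moving_phantom(self,
                                                             diastole_protocol,
                                                             crop_slices):
        rmse_reg, rmse_noreg = [], []
        for seed in range(5):
            spec = PhantomSpec(seed=200 + seed, thermal_sigma=0.0, physio_k=0.0,
                               ti_jitter_frac=0.0)
            series, truth = simulate_series(spec, diastole_protocol)
            myo = truth.myo_mask[crop_slices]
            for use_reg, sink in ((True, rmse_reg), (False, rmse_noreg)):
                pair = preprocess_series(series, register=use_reg)
                out = mbf_map(pair.control_avg, pair.tagged_avg, pair.m0,
                              pair.ti_control_ms, pair.ti_tagged_ms,
                              myo_mask=myo)
                err = out.values[out.analysis_mask] - 1.5
                sink.append(float(np.sqrt(np.mean(err ** 2))))
        assert np.mean(rmse_reg) < np.mean(rmse_noreg)
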