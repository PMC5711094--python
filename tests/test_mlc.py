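import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linacqa.grid import DosePlane, Profile, extract_profile
from linacqa.mlc import (
    analyze_strips,
    compare_pickets,
    default_strip_rois,
    detect_pickets,
    fwhm,
    rcorr,
    strip_deviations,
)
from linacqa.synth import BeamModel, PicketFenceSpec, StripPatternSpec, gen_picket_fence, gen_strip_pair


class TestDetectPickets:
    def test_synthetic_fence_zero_noise(self, ff_beam):
        plane, truth = gen_picket_fence(PicketFenceSpec(count=5), ff_beam, seed=0)
        prof = extract_profile(plane, "cross-plane", 0.0, 5.0)
        peaks = detect_pickets(prof, 5)
        assert np.all(np.abs(peaks - truth) < 0.05)

    def test_triangular_peak_parabolic_refinement(self):
        # triangle apex at 10.3, sampled on integers: the 3-point parabola
        # vertex lands at 10 + 0.5*(-0.6)/(-1.4) = 10.214, within 0.1 px
        x0, width = 10.3, 5.0
        pos = np.arange(0.0, 21.0)
        vals = np.clip(1 - np.abs(pos - x0) / width, 0, None)
        peaks = detect_pickets(Profile(pos, vals), 1)
        assert abs(peaks[0] - (10 + 0.5 * (-0.6) / (-1.4))) < 1e-9
        assert abs(peaks[0] - x0) < 0.1

    def test_uniform_profile_errors(self):
        prof = Profile(np.arange(10.0), np.full(10, 3.0))
        with pytest.raises(ValueError, match="no peaks"):
            detect_pickets(prof, 3)

    def test_wrong_count_reports_found(self, ff_beam):
        plane, _ = gen_picket_fence(PicketFenceSpec(count=5), ff_beam, seed=0)
        prof = extract_profile(plane, "cross-plane", 0.0, 5.0)
        with pytest.raises(ValueError, match="found 5"):
            detect_pickets(prof, 7)

    def test_error_shrinks_with_noise(self, ff_beam):
        # positional error is monotone non-increasing in noise, over seeds
        errs = []
        for noise in (0.05, 0.01, 0.0):
            level = []
            for seed in range(5):
                spec = PicketFenceSpec(count=5, noise_sd=noise)
                plane, truth = gen_picket_fence(spec, ff_beam, seed=seed)
                prof = extract_profile(plane, "cross-plane", 0.0, 5.0)
                level.append(np.abs(detect_pickets(prof, 5) - truth).max())
            errs.append(np.mean(level))
        assert errs[0] >= errs[1] >= errs[2]
        assert errs[2] < 0.05


class TestFwhm:
    def test_rectangular_pulse(self):
        pos = np.arange(-20.0, 20.0, 0.5)
        vals = ((pos >= -5) & (pos < 5)).astype(float)
        w = fwhm(Profile(pos, vals), 0.0)
        assert w == pytest.approx(10.0, abs=0.5)  # within one sample pitch

    def test_gaussian_closed_form(self):
        sigma = 4.0
        pos = np.arange(-30.0, 30.0, 0.05)
        vals = np.exp(-(pos**2) / (2 * sigma**2))
        w = fwhm(Profile(pos, vals), 0.0)
        assert w == pytest.approx(2.3548 * sigma, rel=0.01)

    def test_sloped_background_local_window(self):
        # a peak riding on a ramp: a local background window still finds it
        pos = np.arange(-20.0, 20.0, 0.1)
        vals = 0.02 * pos + np.exp(-(pos**2) / (2 * 1.5**2))
        w = fwhm(Profile(pos, vals), 0.0, background_window=6.0)
        assert w == pytest.approx(2.3548 * 1.5, rel=0.1)

    def test_no_half_crossing_errors(self):
        pos = np.arange(0.0, 10.0)
        vals = np.linspace(1.0, 2.0, 10)  # monotone, no peak drop-off
        with pytest.raises(ValueError):
            fwhm(Profile(pos, vals), 9.0)

    def test_noisy_picket_bias_small(self, ff_beam):
        # Monte-Carlo: FWHM bias under noise stays below 5% of the
        # noiseless value
        clean_plane, truth = gen_picket_fence(PicketFenceSpec(count=3), ff_beam, seed=0)
        clean_prof = extract_profile(clean_plane, "cross-plane", 0.0, 5.0)
        clean_w = fwhm(clean_prof, truth[1], background_window=7.5)
        widths = []
        for seed in range(100):
            spec = PicketFenceSpec(count=3, noise_sd=0.02)
            plane, truth = gen_picket_fence(spec, ff_beam, seed=seed)
            prof = extract_profile(plane, "cross-plane", 0.0, 5.0)
            widths.append(fwhm(prof, truth[1], background_window=7.5))
        assert abs(np.mean(widths) - clean_w) / clean_w < 0.05


class TestComparePickets:
    def test_identical_pass(self):
        ref = np.array([-30.0, -15.0, 0.0, 15.0, 30.0])
        report = compare_pickets(ref, ref)
        assert np.all(report.deviations == 0)
        assert report.passed
        assert not report.flagged.any()

    def test_half_mm_shift_passes_but_flagged(self, ff_beam):
        spec = PicketFenceSpec(count=5, offsets=(0, 0, 0.5, 0, 0))
        plane, _ = gen_picket_fence(spec, ff_beam, seed=0)
        ref_plane, ref_truth = gen_picket_fence(PicketFenceSpec(count=5), ff_beam, seed=0)
        prof = extract_profile(plane, "cross-plane", 0.0, 5.0)
        ref_prof = extract_profile(ref_plane, "cross-plane", 0.0, 5.0)
        report = compare_pickets(detect_pickets(prof, 5), detect_pickets(ref_prof, 5))
        assert report.deviations[2] == pytest.approx(0.5, abs=0.1)
        assert report.passed  # within 1 mm tolerance
        assert report.flagged[2]  # but discernible above 0.25 mm
        assert not report.flagged[[0, 1, 3, 4]].any()

    def test_beyond_tolerance_fails(self):
        ref = np.array([-15.0, 0.0, 15.0])
        test = ref + np.array([0.0, 1.5, 0.0])
        report = compare_pickets(test, ref)
        assert not report.passed
        assert report.max_abs_deviation == pytest.approx(1.5)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compare_pickets(np.array([0.0, 1.0]), np.array([0.0, 1.0, 2.0]))


class TestRcorr:
    def test_published_drgs_value(self):
        assert round(rcorr(74.06, 68.38), 2) == 108.31

    def test_published_lsdr_value(self):
        assert round(rcorr(37.37, 67.12), 2) == 55.68

    def test_equal_readings_give_100(self):
        assert rcorr(68.38, 68.38) == pytest.approx(100.0)

    def test_nonpositive_open_rejected(self):
        with pytest.raises(ValueError):
            rcorr(50.0, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(
        strip=st.floats(0.1, 1e5),
        open_=st.floats(0.1, 1e5),
        c=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, strip, open_, c):
        assert rcorr(c * strip, c * open_) == pytest.approx(rcorr(strip, open_), rel=1e-9)


class TestStripDeviations:
    def test_published_drgs_row(self):
        r = [108.31, 107.01, 106.74, 106.54, 106.39, 106.47, 106.55]
        diffs, summary, passed = strip_deviations(np.array(r))
        assert [round(d, 1) for d in diffs] == [1.4, 0.1, -0.1, -0.3, -0.4, -0.4, -0.3]
        assert round(summary["mean_abs_diff"], 2) == 0.43
        assert passed.all()

    def test_published_lsdr_fff_row(self):
        diffs, summary, _ = strip_deviations(np.array([104.41, 104.78, 104.97, 104.31]))
        assert round(summary["mean_abs_diff"], 2) == 0.25

    def test_all_equal_zero_diffs(self):
        diffs, summary, passed = strip_deviations(np.full(5, 77.7))
        assert np.allclose(diffs, 0.0)
        assert summary["mean_abs_diff"] == 0.0
        assert passed.all()

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(1.0, 200.0), min_size=2, max_size=12)
    )
    def test_deviations_sum_to_zero(self, values):
        diffs, _, _ = strip_deviations(np.array(values))
        assert abs(diffs.mean()) < 1e-9  # algebraic identity of deviation-from-mean


class TestAnalyzeStrips:
    def test_noiseless_all_zero(self, ff_beam):
        strip, open_ = gen_strip_pair(StripPatternSpec(), ff_beam, seed=0)
        res = analyze_strips(strip, open_, default_strip_rois(7, 18.0))
        assert np.all(np.abs(res.table["diff_pct"]) < 1e-10)
        assert res.passed

    def test_injected_scales_recovered(self, ff_beam):
        scales = (1.008, 0.995, 1.0, 1.003, 0.997, 1.0, 1.001)
        strip, open_ = gen_strip_pair(
            StripPatternSpec(scales=scales, noise_sd=0.002), ff_beam, seed=1
        )
        res = analyze_strips(strip, open_, default_strip_rois(7, 18.0))
        s = np.array(scales)
        expected = (s / s.mean() - 1) * 100
        assert np.allclose(res.table["diff_pct"], expected, atol=0.15)

    def test_geometry_mismatch_rejected(self, ff_beam):
        strip, _ = gen_strip_pair(StripPatternSpec(), ff_beam, spacing=0.5, seed=0)
        _, open_ = gen_strip_pair(StripPatternSpec(), ff_beam, spacing=1.0, seed=0)
        with pytest.raises(ValueError, match="geometry"):
            analyze_strips(strip, open_, default_strip_rois(7, 18.0))

    def test_overlapping_rois_rejected(self, ff_beam):
        strip, open_ = gen_strip_pair(StripPatternSpec(), ff_beam, seed=0)
        rois = default_strip_rois(7, 18.0)
        rois[1] = rois[0]
        with pytest.raises(ValueError, match="overlap"):
            analyze_strips(strip, open_, rois)

    def test_four_strip_lsdr_layout(self, ff_beam):
        strip, open_ = gen_strip_pair(
            StripPatternSpec(n_strips=4, strip_width=30.0), ff_beam, seed=0
        )
        res = analyze_strips(strip, open_, default_strip_rois(4, 30.0))
        assert len(res.table) == 4
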