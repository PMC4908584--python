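"""Unit and property tests for the strip-quantification pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stripquant import (
    GrayProfile,
    InputError,
    InvalidTestError,
    LineDetection,
    QuantConfig,
    StripImage,
    analyze,
    assign_lines,
    collapse_profile,
    find_minima,
    smooth,
    tc_ratio,
    to_gray,
)
from stripquant.synthetic import SyntheticStripSpec, render_strip

from conftest import brute_force_minima


def det(index, min_value, baseline):
    return LineDetection(index=index, min_value=min_value,
                         left_baseline=baseline, right_baseline=baseline)


class TestSmooth:
    def test_preserves_constant_image(self):
        img = StripImage(np.full((10, 10), 128, dtype=np.uint8))
        assert np.array_equal(smooth(img).pixels, img.pixels)

    def test_impulse_response_is_binomial_kernel(self):
        px = np.zeros((5, 5), dtype=np.uint8)
        px[2, 2] = 16
        out = smooth(StripImage(px)).pixels
        assert out[2, 2] == 4
        assert out[1, 2] == out[3, 2] == out[2, 1] == out[2, 3] == 2
        assert out[1, 1] == out[1, 3] == out[3, 1] == out[3, 3] == 1

    def test_reduces_iid_noise_variance(self):
        rng = np.random.default_rng(7)
        px = rng.normal(128, 10, size=(200, 200))
        out = smooth(StripImage(px)).pixels
        assert np.var(out[5:-5, 5:-5]) < 0.5 * np.var(px[5:-5, 5:-5])

    def test_rejects_tiny_image(self):
        with pytest.raises(InputError):
            StripImage(np.zeros((2, 5), dtype=np.uint8))

    def test_smooths_each_rgb_channel(self):
        px = np.zeros((5, 5, 3), dtype=np.uint8)
        px[2, 2] = (16, 32, 48)
        out = smooth(StripImage(px)).pixels
        assert tuple(out[2, 2]) == (4, 8, 12)


class TestToGray:
    def test_gray_stays_gray(self):
        px = np.stack([np.full((4, 4), 77, dtype=np.uint8)] * 3, axis=-1)
        assert np.all(to_gray(StripImage(px)).pixels == 77)

    def test_luma_weights_on_pure_red(self):
        px = np.zeros((4, 4, 3), dtype=np.uint8)
        px[..., 0] = 255
        assert np.all(to_gray(StripImage(px)).pixels == 76)  # round(0.299*255)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        img = StripImage(rng.integers(0, 256, size=(6, 6, 3), dtype=np.uint8))
        once = to_gray(img)
        assert np.array_equal(to_gray(once).pixels, once.pixels)


class TestCollapseProfile:
    def test_constant_rows(self):
        img = StripImage(np.full((5, 9), 42, dtype=np.uint8))
        assert np.all(collapse_profile(img).values == 42.0)

    def test_median_suppresses_outlier(self):
        img = StripImage(np.array([[10, 200, 12]] * 3, dtype=np.uint8))
        assert collapse_profile(img).values[0] == 12.0

    def test_length_equals_height_and_even_width_convention(self):
        img = StripImage(np.tile(np.array([[0, 10, 20, 30]], dtype=np.uint8), (7, 1)))
        prof = collapse_profile(img)
        assert len(prof) == 7
        assert prof.values[0] == 15.0  # mean of middle two

    def test_rejects_multichannel(self):
        img = StripImage(np.zeros((4, 4, 3), dtype=np.uint8))
        with pytest.raises(InputError):
            collapse_profile(img)


class TestFindMinima:
    def test_monotone_profile_has_no_minima(self):
        prof = GrayProfile(np.arange(50, 150, 2.0))
        assert find_minima(prof) == []

    @pytest.mark.parametrize("depth,expected", [(9, 0), (10, 1), (30, 1)])
    def test_prominence_threshold_is_bilateral(self, depth, expected):
        vals = np.array([100.0, 100, 100 - depth, 100, 100])
        dets = find_minima(GrayProfile(vals))
        assert len(dets) == expected
        if expected:
            assert dets[0].index == 2
            assert dets[0].depth == depth

    def test_shoulder_only_prominent_on_one_side_rejected(self):
        # dips 30 below the left baseline but only 5 below the right shoulder
        vals = np.array([120.0, 120, 90, 95, 95, 95])
        assert find_minima(GrayProfile(vals)) == []

    def test_plateau_minimum_reports_centre(self):
        vals = np.array([100.0, 100, 80, 80, 80, 100, 100])
        dets = find_minima(GrayProfile(vals))
        assert [d.index for d in dets] == [3]

    def test_two_dips_sorted_by_index(self):
        vals = np.full(60, 200.0)
        vals[15] = 150
        vals[40] = 120
        dets = find_minima(GrayProfile(vals))
        assert [d.index for d in dets] == [15, 40]
        assert [d.depth for d in dets] == [50, 80]

    @settings(max_examples=300, deadline=None)
    @given(st.lists(st.integers(0, 255), min_size=3, max_size=60))
    def test_matches_brute_force_oracle(self, values):
        prof = GrayProfile(np.array(values, dtype=float))
        got = [(d.index, d.min_value, d.left_baseline, d.right_baseline)
               for d in find_minima(prof)]
        assert got == brute_force_minima(values)


class TestAssignLines:
    def test_upstream_detection_is_test_line(self):
        t, c = assign_lines([det(100, 150, 200), det(160, 120, 200)])
        assert (t.index, c.index) == (100, 160)

    def test_two_deepest_kept_among_spurious(self):
        dets = [det(50, 150, 200), det(100, 160, 200), det(160, 188, 200)]
        t, c = assign_lines(dets)
        assert (t.index, c.index) == (50, 100)

    def test_single_detection_is_invalid_test(self):
        with pytest.raises(InvalidTestError):
            assign_lines([det(100, 150, 200)])

    def test_depth_tie_prefers_upstream(self):
        dets = [det(30, 150, 200), det(90, 150, 200), det(150, 150, 200)]
        t, c = assign_lines(dets)
        assert (t.index, c.index) == (30, 90)


class TestTcRatio:
    def test_equal_depths_give_unity(self):
        assert tc_ratio(det(10, 100, 150), det(20, 100, 150)) == 1.0

    def test_half_ratio(self):
        assert tc_ratio(det(10, 170, 200), det(20, 140, 200)) == 0.5

    def test_zero_control_depth_errors(self):
        with pytest.raises(InvalidTestError):
            tc_ratio(det(10, 170, 200), det(20, 200, 200))

    def test_raw_min_mode(self):
        cfg = QuantConfig(tc_mode="raw_min_ratio")
        assert tc_ratio(det(10, 50, 200), det(20, 100, 200), cfg) == 0.5


class TestAnalyze:
    def test_noiseless_round_trip(self):
        spec = SyntheticStripSpec(test_line_depth=40.0, control_line_depth=80.0)
        image, truth = render_strip(spec)
        result = analyze(image)
        assert result.tc == pytest.approx(truth.true_tc_ratio, abs=0.02)
        assert result.test.index == pytest.approx(truth.line_centers_px[0], abs=2)
        assert result.control.index == pytest.approx(truth.line_centers_px[1], abs=2)

    def test_constant_offset_leaves_tc_unchanged(self):
        spec = SyntheticStripSpec(test_line_depth=40.0, control_line_depth=80.0,
                                  background_level=180.0)
        image, _ = render_strip(spec)
        shifted = StripImage(image.pixels + np.uint8(20), px_per_mm=image.px_per_mm)
        assert abs(analyze(shifted).tc - analyze(image).tc) <= 1e-9

    def test_blank_strip_is_invalid_test(self):
        blank = StripImage(np.full((200, 40), 200, dtype=np.uint8))
        with pytest.raises(InvalidTestError) as exc:
            analyze(blank)
        assert exc.value.stage == "assign_lines"

    def test_rgb_strip_matches_grayscale_truth(self):
        spec = SyntheticStripSpec(test_line_depth=48.0, control_line_depth=96.0, rgb=True)
        image, truth = render_strip(spec)
        assert image.n_channels == 3
        assert analyze(image).tc == pytest.approx(truth.true_tc_ratio, abs=0.02)

    def test_roi_crop_excludes_artifact(self):
        spec = SyntheticStripSpec(test_line_depth=40.0, control_line_depth=80.0)
        image, truth = render_strip(spec)
        px = image.pixels.copy()
        px[-5:] = 0  # dark cassette edge at the far end
        cropped = analyze(StripImage(px), QuantConfig(roi=(0.0, 0.9)))
        assert cropped.tc == pytest.approx(truth.true_tc_ratio, abs=0.02)

    def test_log_records_pipeline_stages(self):
        spec = SyntheticStripSpec()
        image, _ = render_strip(spec)
        result = analyze(image)
        joined = " ".join(result.log)
        for stage in ("smooth", "to_gray", "collapse_profile", "find_minima", "tc_ratio"):
            assert stage in joined
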