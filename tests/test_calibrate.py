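"""Depth calibration: profile extraction, inner-fraction restriction,
linear/exponential fits, regime segmentation and depth inversion."""

import numpy as np
import pytest

from conftest import preprocess, render
from hsdepth.calibrate import (
    DepthCalibration,
    Profile,
    extract_profile,
    fit_exponential,
    fit_linear,
    inner_fraction,
    invert_depth,
    segment_regimes,
)
from hsdepth.errors import EmptyProfileError, OutOfRangeError
from hsdepth.isopoint import IsoPointModel, depth_parameter_map
from hsdepth.pipeline import _background_region


@pytest.fixture(scope="module")
def nf_map_and_truth(absorbing_nf_smoothed):
    """Noise-free depth-parameter map at the detected iso-point."""
    smoothed, _, truth = absorbing_nf_smoothed
    res = IsoPointModel.from_cube(smoothed, truth).fit()
    background = _background_region(
        truth, smoothed.pitch_x_um / 1000.0, smoothed.pitch_y_um / 1000.0
    )
    dmap = depth_parameter_map(
        smoothed, res.iso_wavelength - 25.0, res.iso_wavelength, background
    )
    return dmap, truth


class TestExtractProfile:
    def test_along_profile_monotone_with_depth(self, nf_map_and_truth):
        """Noise-free: |d_i| shrinks monotonically as the ramp deepens."""
        dmap, truth = nf_map_and_truth
        profile = extract_profile(dmap, truth, axis="along").labelled()
        shallow = profile.true_depth_mm <= 5.0
        order = np.argsort(profile.true_depth_mm[shallow])
        assert np.all(np.diff(profile.depth_param[shallow][order]) < 0)

    def test_across_profile_wider_than_physical_inclusion(self, nf_map_and_truth):
        """Scattering blur makes the 2 mm inclusion appear wider at half max."""
        dmap, truth = nf_map_and_truth
        ys = np.nonzero(truth.inclusion_mask.any(axis=0))[0]
        y_mm = (ys[len(ys) // 3] + 0.5) * dmap.pitch_y_um / 1000.0
        profile = extract_profile(dmap, truth, axis="across", offset_mm=y_mm)
        mag = np.abs(profile.depth_param)
        half = mag.max() / 2.0
        above = profile.position_mm[mag >= half]
        assert above.max() - above.min() > 2.0

    def test_line_missing_inclusion_signals_empty(self, nf_map_and_truth):
        dmap, truth = nf_map_and_truth
        with pytest.raises(EmptyProfileError):
            extract_profile(dmap, truth, axis="across", offset_mm=1e6)


class TestInnerFraction:
    def test_ten_samples_keep_middle_six(self):
        p = Profile(np.arange(10.0), np.zeros(10), np.zeros(10))
        out = inner_fraction(p, 0.6)
        assert len(out) == 6
        np.testing.assert_array_equal(out.position_mm, np.arange(2.0, 8.0))

    def test_eleven_samples_keep_seven(self):
        p = Profile(np.arange(11.0), np.zeros(11), np.zeros(11))
        assert len(inner_fraction(p, 0.6)) == 7

    def test_fraction_one_is_identity(self):
        p = Profile(np.arange(9.0), np.zeros(9), np.zeros(9))
        assert inner_fraction(p, 1.0) is p

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_fraction_outside_unit_interval_rejected(self, bad):
        p = Profile(np.arange(5.0), np.zeros(5), np.zeros(5))
        with pytest.raises(ValueError):
            inner_fraction(p, bad)


class TestFits:
    def test_exact_line_recovered(self):
        d = np.linspace(0, 8, 12)
        fit = fit_linear((d, 2.0 * d + 1.0))
        assert fit.slope == pytest.approx(2.0, rel=1e-12)
        assert fit.intercept == pytest.approx(1.0, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_parameter_gives_zero_slope_zero_r2(self):
        fit = fit_linear((np.linspace(0, 5, 10), np.full(10, 0.3)))
        assert fit.slope == pytest.approx(0.0, abs=1e-15)
        assert fit.r2 == 0.0

    def test_constant_depth_rejected(self):
        with pytest.raises(ValueError):
            fit_linear((np.full(5, 2.0), np.arange(5.0)))

    def test_noisy_line_slope_within_three_stderr(self, rng):
        d = np.linspace(0, 10, 200)
        y = 2.0 * d + 1.0 + 0.1 * rng.standard_normal(200)
        fit = fit_linear((d, y))
        assert abs(fit.slope - 2.0) <= 3.0 * fit.stderr

    def test_exact_exponential_recovered(self):
        d = np.linspace(0, 10, 20)
        fit = fit_exponential((d, 0.4 * np.exp(-0.5 * d) + 0.01))
        assert fit.amplitude == pytest.approx(0.4, rel=1e-6)
        assert fit.rate == pytest.approx(0.5, rel=1e-6)
        assert fit.offset == pytest.approx(0.01, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_data_reported_degenerate(self):
        fit = fit_exponential((np.linspace(0, 5, 8), np.full(8, 0.2)))
        assert fit.degenerate
        assert fit.amplitude + fit.offset == pytest.approx(0.2)

    def test_deep_regime_profile_is_exponential(self, nf_map_and_truth):
        """The generator's deep regime decays exponentially by construction."""
        dmap, truth = nf_map_and_truth
        p = extract_profile(dmap, truth, axis="along").labelled()
        deep = p.true_depth_mm >= 4.0
        fit = fit_exponential((p.true_depth_mm[deep], p.depth_param[deep]))
        assert fit.r2 >= 0.99


class TestSegmentRegimes:
    def test_pure_linear_data_puts_breakpoint_at_max_depth(self):
        d = np.linspace(0, 10, 21)
        result = segment_regimes((d, 2.0 * d + 1.0))
        assert result.breakpoint_depth == pytest.approx(10.0)
        assert result.exponential is None
        assert result.r2_linear == pytest.approx(1.0)

    def test_glued_piecewise_breakpoint_recovered(self):
        """Linear to 4 mm, exponential beyond, glued continuously."""
        d = np.arange(0.0, 10.25, 0.25)
        bp, slope, icpt = 4.0, -0.004, 0.03
        rate = 0.8
        amp = slope / (-rate * np.exp(-rate * bp))
        off = (slope * bp + icpt) - amp * np.exp(-rate * bp)
        y = np.where(d <= bp, slope * d + icpt, amp * np.exp(-rate * d) + off)
        result = segment_regimes((d, y))
        assert abs(result.breakpoint_depth - bp) <= 0.25 + 1e-9

    def test_piecewise_sse_never_worse_than_single_models(self, rng):
        d = np.linspace(0, 10, 60)
        y = 0.03 * np.exp(-0.6 * d) + 1e-4 * rng.standard_normal(60)
        result = segment_regimes((d, y))
        lin = fit_linear((d, y))
        sse_lin = float(np.sum((y - lin(d)) ** 2))
        ex = fit_exponential((d, y))
        sse_exp = float(np.sum((y - ex(d)) ** 2))
        assert result.total_sse <= sse_lin * (1 + 1e-9)
        assert result.total_sse <= sse_exp * (1 + 1e-9)

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError):
            segment_regimes((np.array([1.0, 2.0]), np.array([0.1, 0.2])))


class TestNoisyCalibration:
    def test_inner60_piecewise_r2_with_one_percent_noise(self):
        """At the generator's 1% noise level the inner-60% piecewise fit
        still explains ≥90% of the profile variance."""
        raw, ref, truth = render("absorbing", noise=0.01, seed=11)
        smoothed, _ = preprocess(raw, ref)
        res = IsoPointModel.from_cube(smoothed, truth).fit()
        background = _background_region(truth, 0.26, 0.043)
        dmap = depth_parameter_map(
            smoothed, res.iso_wavelength - 25.0, res.iso_wavelength, background
        )
        profile = extract_profile(dmap, truth, axis="along").labelled()
        fit = DepthCalibration(profile).fit(inner=0.6)
        p = fit.profile
        sst = float(np.sum((p.depth_param - p.depth_param.mean()) ** 2))
        assert 1.0 - fit.result.total_sse / sst >= 0.90


class TestInvertDepth:
    @pytest.fixture
    def two_branch_calibration(self):
        """Hand-built piecewise calibration, continuous at 5 mm."""
        from hsdepth.calibrate import CalibrationResult, ExponentialFit, LinearFit

        bp, slope, icpt, rate = 5.0, -0.004, 0.03, 0.7
        lin = LinearFit(slope, icpt, 1.0, 0.0)
        amp = slope / (-rate * np.exp(-rate * bp))
        off = (slope * bp + icpt) - amp * np.exp(-rate * bp)
        exp = ExponentialFit(amp, rate, off, 1.0)
        return CalibrationResult(bp, lin, exp, 1.0, 1.0, 1.0, 0.0, (0.0, 10.0))

    @pytest.fixture
    def scene_calibration(self, nf_map_and_truth):
        dmap, truth = nf_map_and_truth
        profile = extract_profile(dmap, truth, axis="along").labelled()
        return DepthCalibration(profile).fit(inner=0.6)

    def test_linear_branch_exact_inversion(self, two_branch_calibration):
        r = two_branch_calibration
        di = r.linear.slope * 3.0 + r.linear.intercept
        assert invert_depth(di, r) == pytest.approx(3.0, abs=1e-9)

    def test_exponential_branch_exact_inversion(self, two_branch_calibration):
        r = two_branch_calibration
        di = r.exponential(7.0)
        assert invert_depth(di, r) == pytest.approx(7.0, abs=1e-6)

    def test_unreachable_value_signalled(self, two_branch_calibration):
        with pytest.raises(OutOfRangeError):
            invert_depth(1e6, two_branch_calibration)

    def test_array_input_masks_unreachable(self, two_branch_calibration):
        r = two_branch_calibration
        good = r.linear.slope * 3.0 + r.linear.intercept
        out = invert_depth(np.array([good, 1e6]), r)
        assert not out.mask[0] and out.mask[1]

    def test_round_trip_on_measured_profile(self, scene_calibration):
        """Measured d_i inverted through the calibration recovers depth
        to ≤0.1 mm RMSE over the shallow (linear-regime) window."""
        r = scene_calibration.result
        p = scene_calibration.profile
        lo, hi = scene_calibration.linear_window()
        lin = (p.true_depth_mm >= lo) & (p.true_depth_mm <= hi)
        pred = invert_depth(p.depth_param[lin], r)
        ok = ~np.ma.getmaskarray(pred)
        # a sample at the very edge of the calibrated range may invert
        # marginally outside it and be flagged; all others must resolve
        assert ok.sum() >= lin.sum() - 1
        rmse = float(np.sqrt(np.mean((pred[ok] - p.true_depth_mm[lin][ok]) ** 2)))
        assert rmse <= 0.1

    def test_summary_reports_fitted_regimes(self, scene_calibration):
        text = scene_calibration.summary()
        assert "regime" in text and "breakpoint" in text
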