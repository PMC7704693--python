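"""TDC extraction, SVD-deconvolution CBF, and temporal curve metrics."""

import numpy as np
import pytest

from kwia.containers import DynamicSeries
from kwia.metrics import ROI
from kwia.perfusion import (
    FWHMUndefinedError,
    PerfusionConfig,
    TimeDensityCurve,
    curve_auc,
    curve_fwhm,
    curve_rmse,
    extract_tdc,
    svd_deconvolve,
)
from kwia.phantoms import gamma_variate, render_perfusion_rod_phantom, tissue_curve

# frozen from bisection on the alpha=11 gamma variate (normalized time)
GAMMA11_FWHM_TAU = 0.712493

AIF = gamma_variate(np.arange(40.0), 12.0, 3.0, c0=0.008)


def _tdc(values, dt=1.0):
    return TimeDensityCurve(np.asarray(values, float), dt)


class TestExtractTdc:
    def test_constant_series_gives_zero_curve(self):
        series = DynamicSeries(np.full((5, 16, 16), 3.0), 1.0, 1.0)
        roi = ROI("circle", (8, 8), 4)
        tdc = extract_tdc(series, roi, baseline_frames=2)
        np.testing.assert_array_equal(tdc.values, 0.0)

    def test_single_pixel_roi_is_pixel_time_course(self):
        rng = np.random.default_rng(0)
        frames = rng.random((6, 8, 8))
        series = DynamicSeries(frames, 1.0, 1.0)
        roi = ROI("circle", (3, 5), 0.1)
        tdc = extract_tdc(series, roi, baseline_frames=0)
        np.testing.assert_allclose(tdc.values, frames[:, 3, 5])

    def test_empty_roi_rejected(self):
        series = DynamicSeries(np.zeros((3, 8, 8)), 1.0, 1.0)
        mask = np.zeros((8, 8), bool)
        with pytest.raises(ValueError, match="empty"):
            extract_tdc(series, ROI("mask", mask_array=mask))


class TestSvdDeconvolution:
    # light truncation: the rod-phantom curves are noiseless or lightly
    # noisy, so little regularization is needed
    config = PerfusionConfig(svd_truncation_fraction=0.01)

    def test_zero_tissue_gives_zero_cbf(self):
        cbf, _ = svd_deconvolve(_tdc(np.zeros(40)), _tdc(AIF), self.config)
        assert cbf == 0.0

    @pytest.mark.parametrize("cbf_true", [30.0, 60.0, 90.0])
    def test_closed_loop_recovery_within_5pct(self, cbf_true):
        """Known flow is recovered within 5% from a noiseless tissue curve."""
        c = tissue_curve(AIF, cbf_true, "exponential", mtt=4.0, frame_interval=1.0)
        cbf, residue = svd_deconvolve(_tdc(c), _tdc(AIF), self.config)
        assert cbf == pytest.approx(cbf_true, rel=0.05)

    def test_linearity_in_tissue_amplitude(self):
        c = tissue_curve(AIF, 50.0, "exponential", mtt=4.0, frame_interval=1.0)
        cbf1, _ = svd_deconvolve(_tdc(c), _tdc(AIF), self.config)
        cbf2, _ = svd_deconvolve(_tdc(2 * c), _tdc(AIF), self.config)
        assert cbf2 == pytest.approx(2 * cbf1, rel=1e-9)

    def test_joint_rescaling_invariance(self):
        """Scaling AIF and tissue together leaves CBF unchanged."""
        c = tissue_curve(AIF, 50.0, "exponential", mtt=4.0, frame_interval=1.0)
        cbf1, _ = svd_deconvolve(_tdc(c), _tdc(AIF), self.config)
        cbf2, _ = svd_deconvolve(_tdc(3 * c), _tdc(3 * AIF), self.config)
        assert cbf2 == pytest.approx(cbf1, rel=1e-9)

    def test_zero_aif_rejected(self):
        with pytest.raises(ValueError, match="AIF"):
            svd_deconvolve(_tdc(np.ones(10)), _tdc(np.zeros(10)))

    def test_noise_drives_cbf_overestimation(self):
        """Mean recovered CBF grows monotonically with added noise level."""
        cbf_true = 60.0
        c = tissue_curve(AIF, cbf_true, "exponential", mtt=4.0, frame_interval=1.0)
        rng = np.random.default_rng(42)
        peak = c.max()
        means = []
        for level in (0.0, 0.02, 0.05, 0.1):
            vals = []
            for _ in range(150):
                noisy = c + rng.normal(0, level * peak, size=c.size)
                cbf, _ = svd_deconvolve(_tdc(noisy), _tdc(AIF), self.config)
                vals.append(cbf)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2] < means[3]

    def test_rod_phantom_closed_loop(self):
        """CBF recovered from the rendered rod phantom matches the truth."""
        cbf_true = 45.0
        series = render_perfusion_rod_phantom(AIF, cbf_true, "exponential", mtt=4.0)
        meta = series.meta
        rods = {
            k: ROI.circle_mm(meta["rod_centers"][k], meta["rod_radius"] / 2, 128, 1.5)
            for k in ("artery", "tissue1")
        }
        aif = extract_tdc(series, rods["artery"], baseline_frames=1)
        tis = extract_tdc(series, rods["tissue1"], baseline_frames=1)
        cbf, _ = svd_deconvolve(tis, aif, self.config)
        assert cbf == pytest.approx(cbf_true, rel=0.05)


class TestCurveMetrics:
    def test_triangle_curve_auc_and_fwhm(self):
        tri = _tdc([0.0, 1.0, 0.0])
        assert curve_auc(tri) == pytest.approx(1.0)
        assert curve_fwhm(tri) == pytest.approx(1.0)

    def test_identical_curves_zero_rmse(self):
        a = _tdc(AIF)
        assert curve_rmse(a, a) == 0.0

    def test_sampled_gamma_fwhm_near_continuous_value(self):
        """27 frames at 2 s sample the alpha=11 bolus finely enough that the
        interpolated FWHM is within 10% of the continuous-curve value."""
        t = np.arange(27) * 2.0
        curve = _tdc(gamma_variate(t, 20.0, 11.0), dt=2.0)
        fwhm = curve_fwhm(curve)
        assert fwhm == pytest.approx(GAMMA11_FWHM_TAU * 20.0, rel=0.10)

    def test_fwhm_undefined_signaled(self):
        with pytest.raises(FWHMUndefinedError):
            curve_fwhm(_tdc([0.0, 0.5, 1.0]))  # never falls below half max


class TestCbfMap:
    def test_rod_phantom_map_recovers_flow_in_tissue(self):
        """The CBF map over the tissue rod reads the ground-truth flow."""
        from kwia.perfusion import cbf_map

        cbf_true = 60.0
        series = render_perfusion_rod_phantom(AIF, cbf_true, "exponential", mtt=4.0)
        meta = series.meta
        art = ROI.circle_mm(meta["rod_centers"]["artery"], meta["rod_radius"] / 2, 128, 1.5)
        tis = ROI.circle_mm(meta["rod_centers"]["tissue1"], meta["rod_radius"] / 2, 128, 1.5)
        aif = extract_tdc(series, art, baseline_frames=1)
        cfg = PerfusionConfig(svd_truncation_fraction=0.01, baseline_frames=1)
        m = cbf_map(series, aif, cfg, mask=tis.mask((128, 128)))
        vals = m[tis.mask((128, 128))]
        assert np.median(vals) == pytest.approx(cbf_true, rel=0.05)
        assert m[0, 0] == 0.0  # outside the mask
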