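"""Closed-loop CBF quantification on the rod-based perfusion phantom.

The phantom's tissue rods enhance as the indicator-dilution convolution of
the arterial input function with an exponential residue at a known flow.
Truncated-SVD deconvolution should recover that flow; with added image
noise the estimate drifts upward (the well-known SVD overestimation).
"""

import numpy as np

from kwia import (
    PerfusionConfig,
    TimeDensityCurve,
    curve_auc,
    curve_fwhm,
    extract_tdc,
    gamma_variate,
    render_perfusion_rod_phantom,
    svd_deconvolve,
)
from kwia.metrics import ROI
from kwia.phantoms import tissue_curve

aif = gamma_variate(np.arange(40.0), 12.0, 3.0, c0=0.008)
cbf_true = 60.0

series = render_perfusion_rod_phantom(aif, cbf_true, "exponential", mtt=4.0)
meta = series.meta
roi = lambda k: ROI.circle_mm(meta["rod_centers"][k], meta["rod_radius"] / 2, 128, 1.5)

aif_tdc = extract_tdc(series, roi("artery"), baseline_frames=1)
tis_tdc = extract_tdc(series, roi("tissue1"), baseline_frames=1)
config = PerfusionConfig(svd_truncation_fraction=0.01)
cbf, residue = svd_deconvolve(tis_tdc, aif_tdc, config)

print(f"true CBF {cbf_true:.1f} ml/100g/min -> recovered {cbf:.1f} "
      f"({100 * cbf / cbf_true - 100:+.1f}%)")
print(f"AIF: AUC {curve_auc(aif_tdc):.4f}, FWHM {curve_fwhm(aif_tdc):.1f} s")

print("\nwith zero-mean noise added to the tissue curve (200 draws each):")
c = tissue_curve(aif, cbf_true, "exponential", mtt=4.0, frame_interval=1.0)
rng = np.random.default_rng(7)
for level in (0.0, 0.02, 0.05, 0.1):
    vals = [
        svd_deconvolve(
            TimeDensityCurve(c + rng.normal(0, level * c.max(), c.size), 1.0),
            TimeDensityCurve(aif, 1.0),
            config,
        )[0]
        for _ in range(200)
    ]
    print(f"  noise {level:4.2f} x peak: mean CBF {np.mean(vals):5.1f}")
# the mean estimate rises with the noise level: SVD deconvolution
# overestimates perfusion on noisy data, which is why recovering SNR with
# KWIA also corrects CBF bias in low-dose scans
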