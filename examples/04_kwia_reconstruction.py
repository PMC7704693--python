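"""Reconstruct a low-dose dynamic scan with KWIA and measure SNR recovery.

A small dynamic disk phantom is projected, dosed down with Poisson noise,
and reconstructed three ways: plain regridding at full dose, plain
regridding at half dose, and KWIA (3 rings) at half dose.  KWIA averages
the outer k-space rings over neighboring time frames, recovering the SNR
lost to the dose reduction while ring 1 keeps each frame's contrast.
"""

import numpy as np

from kwia import (
    DoseConfig,
    ProjectionGeometry,
    RingSpec,
    Sinogram,
    counts_from_line_integrals,
    forward_project_parallel,
    line_integrals_from_counts,
    reconstruct_kwia_series,
    regrid_reconstruct,
)
from kwia.metrics import ROI, roi_snr

n, h = 128, 1.5
geom = ProjectionGeometry("parallel", 182, h, 288)
c = (n - 1) / 2
y, x = np.mgrid[:n, :n]
img = np.where(((x - c) ** 2 + (y - c) ** 2) * h * h <= 70.0**2, 0.019, 0.0)
clean_sino = forward_project_parallel(img, h, geom)

n_frames, ne = 8, 4.8e6


def noisy_series(dose, seed0):
    out = []
    for f in range(n_frames):
        counts = counts_from_line_integrals(clean_sino, DoseConfig(ne, dose, seed0 + f))
        out.append(line_integrals_from_counts(counts, dose * ne, clean_sino))
    return out


roi = ROI("circle", (c, c), 25)
clean_rec = regrid_reconstruct(clean_sino, final_size=n)

full = regrid_reconstruct(noisy_series(1.0, 100)[4], final_size=n)
half_sinos = noisy_series(0.5, 200)
half = regrid_reconstruct(half_sinos[4], final_size=n)
rings = RingSpec.from_dose(geom.n_parallel_views, geom.n_detectors, np.sqrt(0.5), 3)
kwia = reconstruct_kwia_series(half_sinos, rings, final_size=n, frame_indices=[4])

snr = {
    "full dose": roi_snr(full, roi, noise_image=full - clean_rec),
    "50% dose": roi_snr(half, roi, noise_image=half - clean_rec),
    "KWIA 50% 3R": roi_snr(
        kwia.frames[0], roi, noise_image=kwia.frames[0] - clean_rec
    ),
}
print(f"ring radii {list(rings.radii)}, windows {list(rings.window_sizes)}")
for k, v in snr.items():
    print(f"  {k:12s}: uniform-ROI SNR = {v:6.1f} ({100 * v / snr['full dose']:.0f}% of full)")
# expected pattern: 50% dose sits near 71% of full-dose SNR, and the
# 3-ring KWIA reconstruction recovers it to roughly full-dose level
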