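"""Render the dynamic head phantom and forward-project one frame.

The phantom is a FORBILD-like head (skull, brain, ventricles) with three
vessels of 10, 5 and 2.5 mm whose enhancement follows a gamma-variate
bolus (alpha = 11, peak at the 10th of 27 frames).
"""

import numpy as np

from kwia import ProjectionGeometry, forbild_head_spec, forward_project_parallel
from kwia.phantoms import mu_to_hu, render_dynamic_phantom

spec = forbild_head_spec(image_size=192, pixel_spacing=1.5, n_frames=27)
series = render_dynamic_phantom(spec)
peak_frame = series.frames[10]

print(f"phantom: {series.n_frames} frames of {peak_frame.shape}, "
      f"{spec.pixel_spacing} mm pixels, {spec.frame_interval} s interval")
print(f"brain attenuation ~ {peak_frame[96, 120]:.5f} mm^-1 "
      f"({mu_to_hu(peak_frame[96, 120]):.0f} HU)")

geom = ProjectionGeometry("parallel", 364, 1.5, 576)
sino = forward_project_parallel(peak_frame, spec.pixel_spacing, geom)
print(f"sinogram: {sino.values.shape} (views x detectors), "
      f"line integrals up to {sino.values.max():.2f}")

# the 10 mm vessel's enhancement curve, sampled at the frame times
v = spec.vessels[0]
curve = v.enhancement(spec.frame_times, spec.frame_interval)
print("vessel enhancement (fraction of peak) at frames 0..26:")
print(np.array2string(curve / v.c0, precision=2, max_line_width=78))
# the curve is zero at the start, peaks (1.00) at frame 10 = 20 s, and
# decays with the alpha = 11 gamma-variate tail
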