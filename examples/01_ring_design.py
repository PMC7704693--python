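"""Design KWIA k-space rings for a low-dose CT-perfusion scan.

The central ring must be small enough that its denser radial sampling
compensates the SNR lost to tube-current reduction: R1 = (N_proj/pi) rSNR.
Outer rings interpolate linearly out to the k-space edge N_det/2.
"""

import numpy as np

from kwia import RingSpec, nyquist_radius, ring1_radius, ring_radii
from kwia.rings import RING_PRESETS

n_parallel_views = 1152 // 2  # distinct parallel angles over 180 degrees
n_detectors = 728

print(f"Nyquist-complete k-space radius: {nyquist_radius(n_parallel_views):.1f} samples")
for dose in (0.5, 0.25):
    rsnr = np.sqrt(dose)
    r1 = ring1_radius(n_parallel_views, rsnr)
    print(f"\ndose fraction {dose:.2f} (relative SNR {rsnr:.3f}): ring 1 radius = {r1}")
    for n_rings in (2, 3, 4):
        radii = ring_radii(nyquist_radius(n_parallel_views) * rsnr, n_detectors, n_rings)
        spec = RingSpec.from_dose(n_parallel_views, n_detectors, rsnr, n_rings)
        print(f"  {n_rings} rings: radii {radii}, windows {list(spec.window_sizes)}")

print("\nshipped presets (published radii):")
for name in ("kwia50-2ring", "kwia50-3ring", "kwia25-3ring", "kwia25-4ring"):
    s = RING_PRESETS[name]
    print(f"  {name}: radii {list(s.radii)}, windows {list(s.window_sizes)}")

# The ring-1 radii printed above (130 for 50% dose, 92 for 25%) shrink with
# dose: a lower-dose scan needs a smaller fully-sampled center to keep its
# effective SNR, and wider outer rings that borrow data from neighbors.
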