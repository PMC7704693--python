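# kwia — low-dose CT perfusion by k-space weighted image average

CT perfusion (CTP) tracks a contrast bolus through the brain with repeated
CT scans, which makes it one of the highest-dose neuroimaging exams
(~200 mGy).  Reducing the X-ray tube current by a fraction *f* cuts dose
proportionally but multiplies image SNR by √*f*, and the resulting noise
biases SVD-based perfusion quantification upward.

**KWIA** (k-space weighted image average) recovers that SNR without extra
hardware or iterative reconstruction.  By the central slice theorem, the 1D
FFT of each parallel-beam projection is a radial spoke of the image's 2D
Fourier transform, so a CTP frame's sinogram becomes a radial "k-space".
KWIA divides this k-space into concentric rings:

* **Ring 1** (|k| ≤ R₁) always uses the current time frame alone, preserving
  image contrast and temporal resolution;
* outer rings are averaged over progressively wider windows of neighboring
  frames (sizes 1, 2, 4, 8 …), trading temporal footprint at high spatial
  frequencies for noise reduction.

The ring-1 radius follows from the radial Nyquist radius *R = N_proj/π*
scaled by the relative SNR of the low-dose scan,

&nbsp;&nbsp;&nbsp;&nbsp;R₁ = (N_proj/π) · rSNR,&nbsp;&nbsp;
R_n = R₁ + (N_det/2 − R₁)(n−1)/(N_rings−1),

with *N_proj* the distinct parallel angles over 180° (e.g. 576 for 1152
views/rotation).  For 50% dose (rSNR = √0.5) this gives R₁ = 130; for 25%
dose, R₁ = 92.  After ring-wise averaging, the radial data are density
compensated with Voronoi cell areas, regridded onto a Cartesian grid with a
Kaiser-Bessel kernel (β = 16.25, width 7, oversampling 2), inverse-FFT'd
and deapodized.

The package contains everything needed to simulate and evaluate this
end to end:

| module | contents |
|---|---|
| `kwia.geometry` | projection geometry, Joseph-style parallel projector, fan→parallel rebinning |
| `kwia.phantoms` | dynamic FORBILD-like head phantom (gamma-variate vessels), rod perfusion phantom |
| `kwia.noise` | Poisson counts from line integrals, dose-reduction noise injection, √dose SNR law |
| `kwia.kspace`, `kwia.rings`, `kwia.recon` | radial FFT, Voronoi weights, Kaiser-Bessel gridding, ring design, KWIA chain |
| `kwia.baselines` | Ram-Lak / Hann / Shepp-Logan filtered back projection, plain regridding |
| `kwia.perfusion`, `kwia.metrics` | TDC extraction, truncated-SVD CBF, AUC/FWHM/RMSE, ROI SNR/CNR, Bland-Altman |
| `kwia.studies`, `kwia.cli` | pre-assembled simulation studies, YAML study runner, `kwia` command line |

## Worked example

`examples/04_kwia_reconstruction.py` projects a dynamic disk phantom,
simulates half-dose Poisson noise at N_e = 4.8×10⁶ photons, and compares
plain regridding with a 3-ring KWIA reconstruction:

```
ring radii [32, 62, 91], windows [1, 2, 4]
  full dose   : uniform-ROI SNR =  232.4 (100% of full)
  50% dose    : uniform-ROI SNR =  170.4 (73% of full)
  KWIA 50% 3R : uniform-ROI SNR =  293.8 (126% of full)
```

Half dose costs ~√2 of SNR (73% ≈ 70.7% theory); KWIA's view sharing more
than recovers it, because ring 2 and 3 noise is averaged over 2 and 4
frames.  `examples/05_perfusion_cbf.py` closes the loop on perfusion: a
rod phantom built with known CBF = 60 ml/100g/min is recovered at
59.0 ml/100g/min by truncated-SVD deconvolution, and the same estimator
drifts to 88.8 ml/100g/min when 10%-of-peak noise is added — the
overestimation that motivates recovering SNR before quantification.
The other examples cover ring design, phantom rendering and the
square-root dose law; each prints a short interpretation of its numbers.

There is also a thin CLI mirroring the pipeline stages:

```bash
kwia simulate --frames 27 sim.h5
kwia noise --dose 0.5 --ne 4.8e6 --seed 17 sim.h5 low.h5
kwia recon --method kwia --preset kwia50-3ring low.h5 out.nii.gz
kwia study src/kwia/presets/digital_phantom.yaml outdir/
```

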