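# Methods

This note records the models, conventions and numerical choices behind the
package, and what its synthetic studies do and do not demonstrate.

## Geometry and forward model

Images are square attenuation maps in mm⁻¹ with the isocenter at pixel
((N−1)/2, (N−1)/2); detector offsets are symmetric about the central ray,
t_d = (d − (D−1)/2)·s; view angles are CCW from +x.  A parallel projection
is the Radon transform p(θ, t) = ∫ μ ds (dimensionless line integrals).

The main projector is Joseph-style: it steps along the image axis most
aligned with the ray, interpolating linearly along the other axis, with
path factor s/max(|cos θ|, |sin θ|).  It is linear and conserves mass to
<1%; against a 0.1-pixel ray-marching integrator it agrees to <0.5%
relative L2.  Fan-beam data (equiangular arc) are rebinned to parallel
geometry via γ = asin(t/SID), β = φ − γ with bilinear interpolation; a full
rotation is required, and the output has half as many views over 180°.

## Photon noise model

Detected counts are Poisson with mean f·N_e·e^(−l), where N_e is the
full-dose emitted photon count per detector per view (default 4.8×10⁶, a
clinical-equivalent estimate) and f ∈ (0, 1] is the tube-current fraction.
Two simplifications are adopted deliberately: the compound detector
process is approximated as Poisson, and electronic (Gaussian) read-out
noise is ignored.  Consequently detector SNR is √(N_e e^(−l)) and
reconstructed-image SNR scales with √f.

For data that are already noisy (no noiseless ground truth), dose
reduction is simulated by adding an independent zero-mean Poisson-derived
term: output = f·counts + (Poisson(v) − v) with v = (f − f²)·counts, which
uses the observed counts as the estimate of N_e·e^(−l).  The output then
has both the mean and the variance of a genuine scan at fraction f.
Reduced-dose counts are log-converted against the *effective* photon
count f·N_e (the air calibration a scanner would perform at that tube
current); counts are floored at one photon before the log.  Streak
artifacts from photon starvation are out of scope.

## KWIA reconstruction chain

1. **Radial FFT** — per-view 1D FFT of the parallel projections, phased to
   the isocenter, DC at the central radial index.  For a real image the
   spokes are conjugate-symmetric; the DC sample of every view equals the
   object mass.
2. **Ring averaging** — ring n covers R_{n−1} < |k| ≤ R_n (hard
   boundaries, DC in ring 1).  Samples in ring n are averaged over M_n
   frames with uniform weights 1/M_n and centered offsets
   ⌈−(M−1)/2⌉ … ⌈(M−1)/2⌉ ({0,+1} for M = 2; {−1,0,+1,+2} for M = 4);
   at the series ends the whole window slides to stay in range, keeping
   its size.  Ring 1 (M = 1) passes the frame through bit-for-bit.
   Default windows are 1, 2, 4, 8 for rings 1–4.  Averaging operates on
   the post-log attenuation projections.
3. **Density compensation** — Voronoi cell areas of the 2D sample cloud
   (guard samples two cells beyond the edge bound the outer cells; the
   outermost cells are clipped to the max-|k| disk analytically; the
   duplicated DC sample is treated as one shared point).  Interior weights
   match the analytic ramp |k|·π/N_views to <2%; the tessellation is
   cached per geometry because it is by far the most expensive one-time
   step (~25 s at 576×728).
4. **Regridding** — separable Kaiser-Bessel kernel, β = 16.25, width 7
   oversampled cells, oversampling 2, evaluated from a 4096-entry lookup
   table; accumulation by per-offset `bincount`.
5. **Inverse FFT + deapodization** — 2D inverse FFT of the oversampled
   grid, division by the kernel's analytic transform (masked below 10⁻⁸
   of its peak), central crop.  A half-pixel phase ramp applied before
   gridding aligns the FFT grid with the ((N−1)/2) image convention, so
   forward projection and reconstruction share one coordinate system.

The chain reproduces a direct nonuniform-DFT reconstruction to ~10⁻⁷
relative L2 (the remaining ~1.5% disk-reconstruction RMSE is shared with
the NDFT and stems from the coarse radial quadrature near DC plus Gibbs
ringing at the hard edge, not from gridding).  With a single ring the
chain reduces exactly to plain regridding.

FBP uses a frequency-domain ramp filter zero-padded to the next power of
two ≥ 2× the detector count (avoiding circular wrap), optional Hann /
Shepp-Logan windows, and linear-interpolation back projection scaled by
π/N_views.  The filtered projections are sinc-upsampled 4× (spectral
zero-padding) before interpolation: plain linear interpolation has a
sinc² roll-off that passes only 40% of the noise power at the detector
Nyquist, which would make FBP noise ~1.4× lower than the gridding
chain's on identical data; after upsampling the two methods' uniform-ROI
SNRs agree to ~2%.

The disk-accuracy figures quoted here and asserted in tests are measured
at the full study geometry (728 detectors, 576 parallel views).  At much
smaller fixture geometries the radial quadrature near DC becomes coarse
(the object transform's main lobe spans ~1 radial sample) and both
methods degrade to 3–5% RMSE; that is a property of the problem scale,
not of either implementation.

## Digital head-phantom study

The shipped phantom is FORBILD-like: skull ellipse (μ = 0.035 mm⁻¹), brain
background (+33 HU over water at 0.0184 mm⁻¹), two ventricle-like
ellipses (+10 HU), and three vessels of 10, 5, 2.5 mm diameter.  Vessel
enhancement follows C(t) = C₀ τ^α e^(α(1−τ)) with α = 11, τ = t/t_peak,
peaking at the 10th of 27 frames (2 s spacing, 54 s scan).  Following the
FORBILD convention of stating attenuation relative to water, the peak
contrast constant C₀ = 1 corresponds to one water-attenuation unit
(1000 HU equivalent).  Rendering uses 8×8 subpixel area weighting and is
deterministic; the series is linear in (static background, vessel
coverage × C(t)), which the simulator exploits to project four images
instead of 27.

Acquisition keeps the full published geometry — 1152 views/rotation (576
parallel angles), 728 detectors of 0.75 mm — so the published ring-radius
presets apply verbatim (130/364; 130/234/364; 92/182/364; 92/182/273/364,
where the 3-ring middle radii are empirical values kept as printed).  The
phantom is rendered at 384×384 pixels of 0.75 mm (288 mm FOV) rather than
512×512: the head fits with margin, per-pixel noise and all k-space
geometry are unchanged, and the seven-condition study then completes in
minutes on one core.

Measurement conventions:

* **SNR** = ROI mean / noise SD in a uniform brain ROI (circle at
  (40, 20) mm, radius 14 mm).  The SD is measured on the difference
  between the noisy and the noiseless reconstruction of the same frame
  (available by construction), which removes deterministic texture from
  the noise estimate, and the value is averaged over all 27 frames: a
  single ~1100-pixel SD estimate of spatially correlated noise carries a
  few percent sampling error, which would dominate the dose-ratio
  comparison (the expected 2-ring KWIA recovery at 50% dose is
  97.9% ± 0.2, estimated over 12 independent noise realizations at a
  proportionally scaled geometry).
* **TDCs** are ROI means over each vessel's footprint dilated by 1.5 mm
  (2 pixels): the gridding reconstruction redistributes part of a small
  vessel's signal into a local edge response, and a footprint-only ROI
  would misread that redistribution as temporal infidelity (for the
  2.5 mm vessel it triples the apparent KWIA-vs-full-dose RMSE).  Curves
  are baseline subtracted (3 pre-contrast frames; the bolus is < 10⁻³ of
  peak before frame 3) and normalized by the full-dose curve's peak.
  AUC is trapezoidal, FWHM interpolates the two half-maximum crossings,
  RMSE is pointwise against the full-dose curve.
* **Baseline sharing.**  Every condition reconstructs the same static
  phantom, so one common pre-contrast baseline (mean of the full-dose
  curve's first three frames) is subtracted from all conditions.  With
  per-condition baselines, the independent 3-frame baseline error is
  amplified by the 52 s integration and dominates the AUC differences
  (~1% standard deviation); sharing the baseline cancels it exactly in
  the between-condition comparison.  ``extract_tdc`` keeps per-curve
  baseline subtraction as its default, which is the right convention for
  real data where conditions do not share an acquisition.

## Perfusion quantification

Tissue enhancement is modeled as C_t = (ρ·CBF/6000)·Δt·(A·R) with the
lower-triangular AIF Toeplitz matrix A (rectangle rule), tissue density
ρ = 1.04 g/ml, hematocrit correction unity, and R an exponential or box
residue.  Deconvolution inverts A by SVD, zeroing singular values below a
fraction of the largest; CBF = (6000/ρ)·max(k).  The default truncation of
0.2 is a conventional robust choice for noisy clinical curves; the rod-
phantom analyses use 0.01 because their curves are noiseless or lightly
noisy, and heavier truncation smooths the residue peak and biases CBF low
(−10% at 0.05, −40% at 0.2 on the shipped AIF).  The standard
(delay-sensitive) formulation is used; block-circulant variants and
CBV/MTT maps are out of scope.  With noise added to the tissue curve the
mean CBF estimate rises monotonically — the known overestimation direction
of truncated-SVD deconvolution.

## What the synthetic studies do and do not show

The phantoms exercise the reconstruction and quantification chains under
exactly known geometry, dynamics and noise.  They do not model beam
hardening, scatter, detector crosstalk, bowtie filtration, patient motion,
kVp effects or anatomical texture; absolute SNR/CNR values therefore
depend on the chosen phantom attenuations and are not comparison targets —
only ratios between dose conditions and differences between reconstruction
methods are.  Fan-beam rebinning is provided for real-data workflows but
the simulated studies generate parallel-beam data directly.

## Degenerate inputs and tie-breaks

Ring radii are rounded half-up with R₁ kept unrounded inside the
interpolation; a one-ring spec means "no view sharing" and equals plain
regridding.  FWHM raises a distinct error when a half-maximum crossing is
missing; SNR/CNR raise distinct errors on zero-variance ROIs; negative CBF
estimates are clipped to zero with a warning.  All stochastic operations
take explicit seeds and are bit-reproducible.
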