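"""Pre-assembled simulation studies.

Two reusable study engines drive both the command-line ``kwia study``
pipeline and the result-reproduction script:

* :func:`noise_law_study` — verifies the square-root dose law on a uniform
  disk phantom: full-dose Poisson counts, dose reduction by zero-mean noise
  injection, FBP reconstruction, and uniform-ROI SNR / noise-SD ratios.
* :func:`digital_phantom_study` — the dynamic head-phantom experiment:
  27-frame gamma-variate bolus, Poisson noise at full/50%/25% dose,
  plain-regridding and KWIA reconstructions, uniform-ROI SNR and
  vessel time-density-curve fidelity (AUC / FWHM / RMSE).

Problem sizes: the head phantom is rendered at 384 x 384 pixels of
0.75 mm (the acquisitions keep the full 1152-views-per-rotation, 728
detector geometry, so the published ring radii apply verbatim); the
noise-law disk runs on a smaller 256-pixel grid, which is ample for ROI
statistics.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baselines import fbp_reconstruct
from .containers import DynamicSeries
from .geometry import ProjectionGeometry, Sinogram, forward_project_parallel
from .kspace import KernelSpec, projections_to_radial_kspace, voronoi_weights
from .metrics import ROI, roi_cnr, roi_snr
from .noise import (
    DEFAULT_N_EMITTED,
    DoseConfig,
    counts_from_line_integrals,
    inject_dose_reduction,
    line_integrals_from_counts,
)
from .perfusion import TimeDensityCurve, curve_auc, curve_fwhm, curve_rmse, extract_tdc
from .phantoms import forbild_head_spec, static_and_vessel_coverage
from .recon import reconstruct_kwia_series, regrid_reconstruct
from .rings import RING_PRESETS, RingSpec

__all__ = ["noise_law_study", "digital_phantom_study", "DigitalStudyConfig"]


def _subseed(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + k) % (2**31 - 1))


# ---------------------------------------------------------------------------
# noise-law study (uniform disk, Eq.-9-style dose injection, FBP)
# ---------------------------------------------------------------------------


def noise_law_study(
    seed: int,
    dose_fractions: tuple[float, ...] = (0.5, 0.25),
    n_repeats: int = 3,
    n_emitted: float = DEFAULT_N_EMITTED,
    image_size: int = 256,
    pixel_spacing: float = 1.0,
    disk_radius_mm: float = 80.0,
    mu: float = 0.019,
) -> dict:
    """Square-root dose law on a uniform disk phantom.

    For each repeat, full-dose counts are drawn from the noiseless disk
    sinogram, reduced-dose counts are generated from them by zero-mean
    noise injection, and every counts sinogram is log-converted and
    reconstructed with Ram-Lak FBP.  The uniform-ROI SNR and noise SD
    (measured on the difference to the noiseless reconstruction) are
    compared to full dose.

    Returns ``{"snr_ratio": {f: %}, "sd_ratio": {f: fold}, ...}`` with
    values averaged over repeats.
    """
    n_views = 2 * int(np.ceil(np.pi / 4 * image_size)) * 2
    geom = ProjectionGeometry("parallel", image_size, pixel_spacing, n_views)
    c = (image_size - 1) / 2.0
    yy, xx = np.mgrid[:image_size, :image_size]
    r2 = ((xx - c) ** 2 + (yy - c) ** 2) * pixel_spacing**2
    img = np.where(r2 <= disk_radius_mm**2, mu, 0.0)
    sino = forward_project_parallel(img, pixel_spacing, geom)

    recon_clean = fbp_reconstruct(sino, output_size=image_size)
    roi = ROI("circle", (c, c), 30.0 / pixel_spacing)

    snr = {f: [] for f in (1.0, *dose_fractions)}
    sd = {f: [] for f in (1.0, *dose_fractions)}
    for rep in range(n_repeats):
        counts_full = counts_from_line_integrals(
            sino, DoseConfig(n_emitted, 1.0, _subseed(seed, 101 + rep))
        )
        per_dose = {1.0: counts_full.astype(float)}
        for j, f in enumerate(dose_fractions):
            per_dose[f] = inject_dose_reduction(
                counts_full, n_emitted, f, _subseed(seed, 301 + 31 * rep + j)
            )
        for f, counts in per_dose.items():
            # air calibration at the actual tube current: f * N_e photons
            noisy = line_integrals_from_counts(counts, f * n_emitted, sino)
            rec = fbp_reconstruct(noisy, output_size=image_size)
            noise_img = rec - recon_clean
            snr[f].append(roi_snr(rec, roi, noise_image=noise_img))
            mask = roi.mask(rec.shape)
            sd[f].append(float(noise_img[mask].std(ddof=1)))

    snr_mean = {f: float(np.mean(v)) for f, v in snr.items()}
    sd_mean = {f: float(np.mean(v)) for f, v in sd.items()}
    return {
        "snr": snr_mean,
        "sd": sd_mean,
        "snr_ratio": {
            f: 100.0 * float(np.mean([a / b for a, b in zip(snr[f], snr[1.0])]))
            for f in dose_fractions
        },
        "sd_ratio": {
            f: float(np.mean([a / b for a, b in zip(sd[f], sd[1.0])]))
            for f in dose_fractions
        },
        "n_repeats": n_repeats,
        "n_views": geom.n_parallel_views,
        "n_detectors": image_size,
    }


# ---------------------------------------------------------------------------
# dynamic digital head-phantom study
# ---------------------------------------------------------------------------


@dataclass
class DigitalStudyConfig:
    """Conditions of the dynamic digital-phantom experiment.

    The seven default conditions are full dose, 50% and 25% dose with
    plain regridding, and KWIA at 50% (2 and 3 rings) and 25% (3 and 4
    rings) with the published ring radii.
    """

    n_detectors: int = 728
    detector_spacing: float = 0.75
    n_views_per_rotation: int = 1152
    n_emitted: float = DEFAULT_N_EMITTED
    image_size: int = 384
    pixel_spacing: float = 0.75
    n_frames: int = 27
    frame_interval: float = 2.0
    # pre-contrast frames (bolus arrives ~frame 4; frame 2 is still clean)
    baseline_frames: int = 3
    # vessel TDC ROIs extend this far beyond the nominal radius so the
    # reconstruction's local edge response stays inside the region
    tdc_roi_margin_mm: float = 1.5
    # uniform brain ROI for SNR, mm about the isocenter (x, y)
    snr_roi_center_mm: tuple[float, float] = (40.0, 20.0)
    snr_roi_radius_mm: float = 14.0
    # second ROI (ventricle) for CNR against the brain ROI
    cnr_roi_center_mm: tuple[float, float] = (14.0, 8.0)
    cnr_roi_radius_mm: float = 5.0
    kwia_conditions: tuple[tuple[str, float, str], ...] = (
        ("kwia50-2ring", 0.5, "kwia50-2ring"),
        ("kwia50-3ring", 0.5, "kwia50-3ring"),
        ("kwia25-3ring", 0.25, "kwia25-3ring"),
        ("kwia25-4ring", 0.25, "kwia25-4ring"),
    )
    kernel: KernelSpec = field(default_factory=KernelSpec)

    @property
    def geometry(self) -> ProjectionGeometry:
        return ProjectionGeometry(
            "parallel", self.n_detectors, self.detector_spacing, self.n_views_per_rotation
        )


def simulate_dynamic_sinograms(config: DigitalStudyConfig, spec=None):
    """Noiseless line-integral sinogram stack of the dynamic head phantom.

    Exploits linearity of the projector: the static background and each
    vessel's coverage mask are projected once and the per-frame sinograms
    assembled as ``static + sum_v C_v(t_f) vessel_v``.

    Returns ``(stack [n_frames, views, detectors], spec, vessel_curves)``.
    """
    if spec is None:
        spec = forbild_head_spec(
            image_size=config.image_size,
            pixel_spacing=config.pixel_spacing,
            n_frames=config.n_frames,
            frame_interval=config.frame_interval,
        )
    geom = config.geometry
    static, covs = static_and_vessel_coverage(spec)
    p_static = forward_project_parallel(static, spec.pixel_spacing, geom).values
    p_vessels = [
        forward_project_parallel(cov, spec.pixel_spacing, geom).values for cov in covs
    ]
    curves = [
        v.enhancement(spec.frame_times, spec.frame_interval) for v in spec.vessels
    ]
    stack = np.empty((spec.n_frames, *p_static.shape))
    for f in range(spec.n_frames):
        frame = p_static.copy()
        for pv, cv in zip(p_vessels, curves):
            frame += cv[f] * pv
        stack[f] = frame
    return stack, spec, curves


def _noisy_line_integrals(
    stack: np.ndarray, geom: ProjectionGeometry, n_emitted: float, dose: float, seed: int
) -> list[Sinogram]:
    """Per-frame Poisson counts at the given dose, log-converted back to
    line integrals."""
    sinos = []
    for f in range(stack.shape[0]):
        template = Sinogram(stack[f], geom)
        counts = counts_from_line_integrals(
            template, DoseConfig(n_emitted, dose, _subseed(seed, 7001 + f))
        )
        # log conversion against the emitted photons at this dose level
        sinos.append(line_integrals_from_counts(counts, dose * n_emitted, template))
    return sinos


def digital_phantom_study(seed: int, config: DigitalStudyConfig | None = None) -> dict:
    """Run the seven-condition dynamic digital-phantom experiment.

    Returns a dictionary with uniform-ROI SNR per condition (and as % of
    full dose), and per-vessel TDC metrics (AUC, FWHM, RMSE on unit-peak
    curves) for full dose and each KWIA condition.
    """
    if config is None:
        config = DigitalStudyConfig()
    geom = config.geometry
    stack, spec, _ = simulate_dynamic_sinograms(config)
    n = config.image_size
    h = config.pixel_spacing

    snr_roi = ROI.circle_mm(config.snr_roi_center_mm, config.snr_roi_radius_mm, n, h)
    cnr_roi = ROI.circle_mm(config.cnr_roi_center_mm, config.cnr_roi_radius_mm, n, h)
    mid = config.n_frames // 2
    vessel_rois = {
        f"{v.diameter:g}mm": ROI.circle_mm(
            v.center, v.diameter / 2.0 + config.tdc_roi_margin_mm, n, h
        )
        for v in spec.vessels
    }

    # warm the Voronoi cache once for this geometry
    voronoi_weights(projections_to_radial_kspace(Sinogram(stack[0], geom)))

    one_ring = RingSpec((config.n_detectors // 2,), (1,))
    clean_series = reconstruct_kwia_series(
        [Sinogram(stack[f], geom) for f in range(config.n_frames)],
        one_ring,
        config.kernel,
        final_size=n,
        frame_interval=config.frame_interval,
    )

    def _mean_snr(series: DynamicSeries) -> float:
        """ROI SNR averaged over every frame; the SD comes from the
        difference to the noiseless reconstruction of the same frame."""
        return float(
            np.mean(
                [
                    roi_snr(
                        series.frames[f],
                        snr_roi,
                        noise_image=series.frames[f] - clean_series.frames[f],
                    )
                    for f in range(series.n_frames)
                ]
            )
        )

    doses_needed = sorted({1.0} | {d for _, d, _ in config.kwia_conditions} | {0.5, 0.25})
    snr = {}
    cnr = {}
    images = {}
    results_tdc: dict[str, dict] = {}
    full_series: DynamicSeries | None = None

    for dose in doses_needed:
        sinos = _noisy_line_integrals(
            stack, geom, config.n_emitted, dose, _subseed(seed, int(1000 * dose))
        )
        label = "full" if dose == 1.0 else f"{int(dose * 100)}%"
        plain_series = reconstruct_kwia_series(
            sinos,
            one_ring,
            config.kernel,
            final_size=n,
            frame_interval=config.frame_interval,
        )
        snr[label] = _mean_snr(plain_series)
        cnr[label] = roi_cnr(plain_series.frames[mid], snr_roi, cnr_roi)
        images[label] = plain_series.frames[mid].copy()
        if dose == 1.0:
            full_series = plain_series
        for name, cond_dose, preset in config.kwia_conditions:
            if cond_dose != dose:
                continue
            rings = RING_PRESETS[preset] if isinstance(preset, str) else preset
            series = reconstruct_kwia_series(
                sinos,
                rings,
                config.kernel,
                final_size=n,
                frame_interval=config.frame_interval,
            )
            snr[name] = _mean_snr(series)
            cnr[name] = roi_cnr(series.frames[mid], snr_roi, cnr_roi)
            images[name] = series.frames[mid].copy()
            results_tdc[name] = {
                vn: extract_tdc(series, r, baseline_frames=0)
                for vn, r in vessel_rois.items()
            }
        del sinos

    assert full_series is not None
    tdc_full = {
        vn: extract_tdc(full_series, r, baseline_frames=0)
        for vn, r in vessel_rois.items()
    }

    # All conditions share the phantom's static content, so one common
    # pre-contrast baseline (from the full-dose series) is subtracted from
    # every condition: differences between conditions then reflect the
    # reconstruction alone, not independent baseline-noise estimates.
    metrics: dict[str, dict] = {}
    for vn, ref in tdc_full.items():
        baseline = float(ref.values[: config.baseline_frames].mean())
        ref_vals = ref.values - baseline
        peak = float(ref_vals.max())
        ref_n = TimeDensityCurve(ref_vals / peak, ref.frame_interval)
        metrics[vn] = {
            "full": {"auc": curve_auc(ref_n), "fwhm": curve_fwhm(ref_n)},
        }
        for cond, curves in results_tdc.items():
            c_n = TimeDensityCurve(
                (curves[vn].values - baseline) / peak, ref.frame_interval
            )
            metrics[vn][cond] = {
                "auc": curve_auc(c_n),
                "fwhm": curve_fwhm(c_n),
                "rmse": curve_rmse(c_n, ref_n),
            }

    snr_ratio = {k: 100.0 * v / snr["full"] for k, v in snr.items() if k != "full"}
    cnr_ratio = {k: 100.0 * v / cnr["full"] for k, v in cnr.items() if k != "full"}
    return {
        "snr": snr,
        "snr_ratio_pct": snr_ratio,
        "cnr": cnr,
        "cnr_ratio_pct": cnr_ratio,
        "mid_frame_images": images,
        "tdc_metrics": metrics,
        "conditions": ["full", "50%", "25%", *results_tdc.keys()],
        "config": config,
    }
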