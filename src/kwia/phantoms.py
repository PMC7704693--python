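"""Dynamic digital phantoms for CT-perfusion simulation.

Two phantoms are provided:

* a FORBILD-like head (skull ring, brain background, two ventricle-like
  low-attenuation ellipses) with three time-varying vessels whose
  enhancement follows a gamma-variate bolus curve, and
* a rod-based perfusion phantom (scan disk with artery / vein / two tissue
  rods) with analytically known AIF, VOF and tissue curves for closed-loop
  testing of CBF quantification.

Attenuation is expressed in mm^-1.  The HU scale used for reporting assumes
water at ``MU_WATER`` (a typical 80 kVp value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import DynamicSeries

__all__ = [
    "MU_WATER",
    "hu_to_mu",
    "mu_to_hu",
    "gamma_variate",
    "VesselDynamics",
    "PhantomSpec",
    "render_dynamic_phantom",
    "render_perfusion_rod_phantom",
    "tissue_curve",
    "forbild_head_spec",
]

MU_WATER = 0.0184
"""Linear attenuation of water in mm^-1 (approximate, 80 kVp)."""


def hu_to_mu(hu: float) -> float:
    """Convert Hounsfield units to linear attenuation (mm^-1)."""
    return MU_WATER * (1.0 + hu / 1000.0)


def mu_to_hu(mu: np.ndarray) -> np.ndarray:
    """Convert linear attenuation (mm^-1) to Hounsfield units."""
    return 1000.0 * (np.asarray(mu) - MU_WATER) / MU_WATER


def gamma_variate(
    t: np.ndarray, peak_time: float, alpha_gamma: float, c0: float = 1.0
) -> np.ndarray:
    """Gamma-variate bolus curve ``C(t) = c0 tau^alpha exp(alpha (1 - tau))``.

    Time is normalized as ``tau = t / peak_time`` so the curve is zero at
    ``t = 0``, rises to its maximum ``c0`` exactly at ``t = peak_time`` and
    decays thereafter; ``alpha_gamma`` sets how fast the signal changes.
    """
    if alpha_gamma <= 0:
        raise ValueError("alpha_gamma must be positive")
    if peak_time <= 0:
        raise ValueError("peak_time must be positive")
    tau = np.asarray(t, dtype=float) / peak_time
    out = np.zeros_like(tau)
    pos = tau > 0
    out[pos] = c0 * tau[pos] ** alpha_gamma * np.exp(alpha_gamma * (1.0 - tau[pos]))
    return out


@dataclass(frozen=True)
class VesselDynamics:
    """A circular vessel with gamma-variate contrast enhancement.

    ``center`` and ``diameter`` are in mm (isocenter origin); ``c0`` is the
    peak added attenuation in mm^-1 on top of ``baseline_attenuation``;
    ``peak_frame`` indexes the frame (0-based) at which enhancement peaks.
    """

    center: tuple[float, float]
    diameter: float
    alpha_gamma: float = 11.0
    c0: float = hu_to_mu(1000.0) - MU_WATER
    peak_frame: int = 10
    baseline_attenuation: float = hu_to_mu(40.0)

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("vessel diameter must be positive")
        if self.alpha_gamma <= 0:
            raise ValueError("alpha_gamma must be positive")

    def enhancement(self, frame_times: np.ndarray, frame_interval: float) -> np.ndarray:
        peak_time = self.peak_frame * frame_interval
        return gamma_variate(frame_times, peak_time, self.alpha_gamma, self.c0)


@dataclass(frozen=True)
class PhantomSpec:
    """Static primitives plus dynamic vessels on a pixel grid.

    ``primitives`` is a list of ``(shape, center_mm, axes_mm, attenuation)``
    with shape ``"ellipse"`` or ``"disk"`` (axes = semi-axes; for a disk both
    semi-axes equal the radius).  Primitives are painted in order, each
    overwriting what is beneath it (with area-weighted anti-aliased edges).
    """

    primitives: tuple
    vessels: tuple
    image_size: int = 384
    pixel_spacing: float = 0.75
    n_frames: int = 27
    frame_interval: float = 2.0

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def fov(self) -> float:
        return self.image_size * self.pixel_spacing


def forbild_head_spec(
    image_size: int = 384,
    pixel_spacing: float = 0.75,
    n_frames: int = 27,
    frame_interval: float = 2.0,
    vessel_c0_hu: float = 1000.0,
) -> PhantomSpec:
    """The shipped FORBILD-like dynamic head preset.

    A skull ellipse (bone) encloses a brain background with two
    ventricle-like low-attenuation ellipses; three vessels of 10, 5 and
    2.5 mm diameter carry a gamma-variate bolus (alpha = 11) peaking at the
    10th time frame.  27 frames at 2 s intervals span a 54 s scan.

    FORBILD-style phantoms state attenuation relative to water; the bolus
    amplitude default of one water-attenuation unit (1000 HU equivalent)
    follows that convention for a peak contrast constant of 1.
    """
    mu_bone = 0.035
    mu_brain = hu_to_mu(33.0)
    mu_csf = hu_to_mu(10.0)
    primitives = (
        ("ellipse", (0.0, 0.0), (80.0, 100.0), mu_bone),
        ("ellipse", (0.0, 0.0), (72.0, 92.0), mu_brain),
        ("ellipse", (-14.0, 8.0), (10.0, 24.0), mu_csf),
        ("ellipse", (14.0, 8.0), (10.0, 24.0), mu_csf),
    )
    c0 = hu_to_mu(vessel_c0_hu) - MU_WATER
    vessels = tuple(
        VesselDynamics(center=ctr, diameter=d, c0=c0)
        for ctr, d in (((-45.0, -40.0), 10.0), ((0.0, -42.0), 5.0), ((40.0, -40.0), 2.5))
    )
    return PhantomSpec(
        primitives,
        vessels,
        image_size=image_size,
        pixel_spacing=pixel_spacing,
        n_frames=n_frames,
        frame_interval=frame_interval,
    )


def _coverage(
    spec: PhantomSpec, center: tuple[float, float], axes: tuple[float, float], subsample: int = 8
) -> np.ndarray:
    """Fractional pixel coverage of an ellipse, by subpixel supersampling."""
    n = spec.image_size
    h = spec.pixel_spacing
    c = (n - 1) / 2.0
    # subpixel center offsets within a pixel, in mm
    sub = (np.arange(subsample) + 0.5) / subsample - 0.5
    cov = np.zeros((n, n), dtype=float)
    # pixel center coordinates in mm: x along axis 1, y along axis 0
    xs = (np.arange(n) - c) * h
    ax, ay = axes
    # bounding box to keep the supersampling cheap
    ix = np.where(np.abs(xs - center[0]) <= ax + h)[0]
    iy = np.where(np.abs(xs - center[1]) <= ay + h)[0]
    if ix.size == 0 or iy.size == 0:
        return cov
    x = xs[ix][None, :, None, None] + sub[None, None, None, :] * h
    y = xs[iy][:, None, None, None] + sub[None, None, :, None] * h
    inside = ((x - center[0]) / ax) ** 2 + ((y - center[1]) / ay) ** 2 <= 1.0
    cov[np.ix_(iy, ix)] = inside.mean(axis=(2, 3))
    return cov


def static_and_vessel_coverage(
    spec: PhantomSpec,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Static frame (vessels at baseline) plus per-vessel coverage masks.

    The dynamic series is linear in these components: frame ``f`` equals
    ``static + sum_v coverage_v * C_v(t_f)``, which downstream code may
    exploit (projection is linear, so a sinogram series can be assembled
    from four projections instead of one per frame).
    """
    half_fov = spec.fov / 2.0
    for v in spec.vessels:
        if (
            abs(v.center[0]) + v.diameter / 2 > half_fov
            or abs(v.center[1]) + v.diameter / 2 > half_fov
        ):
            raise ValueError(f"vessel at {v.center} falls outside the field of view")

    static = np.zeros((spec.image_size, spec.image_size), dtype=float)
    for shape, center, axes, mu in spec.primitives:
        if shape == "disk":
            axes = (axes[0], axes[0]) if np.isscalar(axes) or len(axes) == 1 else axes
        cov = _coverage(spec, tuple(center), tuple(axes))
        static = static * (1 - cov) + mu * cov

    vessel_cov = []
    for v in spec.vessels:
        r = v.diameter / 2.0
        cov = _coverage(spec, v.center, (r, r))
        static = static * (1 - cov) + v.baseline_attenuation * cov
        vessel_cov.append(cov)
    return static, vessel_cov


def render_dynamic_phantom(spec: PhantomSpec) -> DynamicSeries:
    """Rasterize the dynamic phantom into a time series of attenuation maps.

    Frame ``f`` equals the static background plus, for each vessel, its
    coverage mask times ``baseline + C(t_f)``.  Edges are anti-aliased by
    8x8 subpixel area weighting.  Rendering is deterministic.
    """
    static, vessel_cov = static_and_vessel_coverage(spec)
    frames = np.empty((spec.n_frames, spec.image_size, spec.image_size), dtype=float)
    times = spec.frame_times
    for f in range(spec.n_frames):
        frame = static.copy()
        for v, cov in zip(spec.vessels, vessel_cov):
            frame += cov * v.enhancement(times, spec.frame_interval)[f]
        frames[f] = frame
    return DynamicSeries(frames, spec.pixel_spacing, spec.frame_interval)


def tissue_curve(
    aif: np.ndarray,
    cbf: float,
    residue: str,
    mtt: float,
    frame_interval: float,
    rho: float = 1.04,
) -> np.ndarray:
    """Indicator-dilution tissue enhancement for a known flow.

    ``C_t(t) = (rho CBF / 6000) * dt * sum_j AIF(t_j) R(t - t_j)`` with CBF
    in ml/100g/min, tissue density ``rho`` in g/ml and ``R`` either an
    exponential residue ``exp(-t / mtt)`` or a box of width ``mtt``.
    """
    if mtt <= 0:
        raise ValueError("mtt must be positive")
    aif = np.asarray(aif, dtype=float)
    t = np.arange(aif.size) * frame_interval
    if residue == "exponential":
        r = np.exp(-t / mtt)
    elif residue == "box":
        r = (t < mtt).astype(float)
    else:
        raise ValueError(f"unknown residue model {residue!r}")
    flow_per_s = cbf * rho / 6000.0  # ml/100g/min -> fraction per second
    conv = np.convolve(aif, r)[: aif.size]
    return flow_per_s * frame_interval * conv


def render_perfusion_rod_phantom(
    aif_values: np.ndarray,
    cbf_true: float,
    residue: str = "exponential",
    mtt: float = 4.0,
    frame_interval: float = 1.0,
    image_size: int = 128,
    pixel_spacing: float = 1.5,
    vein_delay_frames: int = 3,
) -> DynamicSeries:
    """Render the rod-based perfusion phantom.

    A homogeneous scan disk holds four rods: an "artery" carrying the AIF,
    a "vein" carrying a delayed copy, and two identical "tissue" rods whose
    enhancement is the indicator-dilution convolution of the AIF with the
    chosen residue function at the true flow ``cbf_true`` (ml/100g/min).
    Enhancement values are in attenuation units (mm^-1) on top of a
    water-like background.
    """
    aif_values = np.asarray(aif_values, dtype=float)
    n_frames = aif_values.size
    tis = tissue_curve(aif_values, cbf_true, residue, mtt, frame_interval)
    vof = np.roll(aif_values, vein_delay_frames)
    vof[:vein_delay_frames] = 0.0

    fov = image_size * pixel_spacing
    disk_r = 0.42 * fov
    rod_r = 0.08 * fov
    offs = 0.22 * fov
    spec = PhantomSpec(
        primitives=(("ellipse", (0.0, 0.0), (disk_r, disk_r), MU_WATER),),
        vessels=(),
        image_size=image_size,
        pixel_spacing=pixel_spacing,
        n_frames=n_frames,
        frame_interval=frame_interval,
    )
    base = np.zeros((image_size, image_size))
    cov_disk = _coverage(spec, (0.0, 0.0), (disk_r, disk_r))
    base = MU_WATER * cov_disk
    rods = {
        "artery": ((-offs, 0.0), aif_values),
        "vein": ((offs, 0.0), vof),
        "tissue1": ((0.0, -offs), tis),
        "tissue2": ((0.0, offs), tis),
    }
    covs = {k: _coverage(spec, ctr, (rod_r, rod_r)) for k, (ctr, _) in rods.items()}
    frames = np.empty((n_frames, image_size, image_size), dtype=float)
    for f in range(n_frames):
        frame = base.copy()
        for k, (_, curve) in rods.items():
            frame += covs[k] * curve[f]
        frames[f] = frame
    series = DynamicSeries(frames, pixel_spacing, frame_interval)
    series.meta = {  # rod centers/radii in mm for ROI placement downstream
        "rod_centers": {k: ctr for k, (ctr, _) in rods.items()},
        "rod_radius": rod_r,
    }
    return series
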