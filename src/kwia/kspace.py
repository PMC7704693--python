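"""Radial k-space via the central slice theorem, and regridding reconstruction.

The 1D Fourier transform of each parallel-beam projection is a radial line
(spoke) through the 2D Fourier transform of the object.  Stacking the
transformed projections therefore yields a radial "k-space" of the image,
which is reconstructed by density compensation (Voronoi cell areas),
convolution regridding onto a Cartesian grid with a Kaiser-Bessel kernel,
2D inverse FFT and deapodization.

Coordinates: radial index ``m`` runs from ``-D/2`` to ``D/2 - 1`` (DC at
array index ``D//2``) in units of cycles per detector field of view; the
physical spatial frequency is ``m / (D * detector_spacing)`` cycles/mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi
from scipy.special import i0

from .geometry import Sinogram

__all__ = [
    "KernelSpec",
    "RadialKSpace",
    "projections_to_radial_kspace",
    "voronoi_weights",
    "ramp_weights",
    "regrid_to_cartesian",
    "inverse_fft_and_deapodize",
]


@dataclass(frozen=True)
class KernelSpec:
    """Kaiser-Bessel gridding kernel: shape ``kb_beta``, support ``width``
    (in oversampled grid cells) and grid ``oversampling`` factor.  The
    defaults balance side-lobe suppression against computation time."""

    kb_beta: float = 16.25
    width: int = 7
    oversampling: int = 2

    def __post_init__(self) -> None:
        if self.width < 1 or self.oversampling < 1 or self.kb_beta <= 0:
            raise ValueError("invalid kernel parameters")

    def evaluate(self, u: np.ndarray) -> np.ndarray:
        """Kernel value at distance ``u`` grid cells from the sample."""
        u = np.asarray(u, dtype=float)
        arg = 1.0 - (2.0 * u / self.width) ** 2
        out = np.zeros_like(u)
        ok = arg >= 0
        out[ok] = i0(self.kb_beta * np.sqrt(arg[ok]))
        return out

    def table(self, n: int = 4096) -> tuple[np.ndarray, np.ndarray]:
        """Lookup table of the kernel over [0, width/2] for fast gridding."""
        u = np.linspace(0.0, self.width / 2.0, n)
        return u, self.evaluate(u)

    def deapodization(self, n: int) -> np.ndarray:
        """Analytic inverse transform of the kernel, sampled at the ``n``
        pixels of the oversampled image (center at index ``n // 2``)."""
        x = (np.arange(n) - n // 2) / float(n)  # cycles per grid cell
        z = np.emath.sqrt(self.kb_beta**2 - (np.pi * self.width * x) ** 2)
        with np.errstate(invalid="ignore"):
            c = np.where(np.abs(z) < 1e-12, 1.0, np.real(np.sinh(z) / z))
        return self.width * c


@dataclass
class RadialKSpace:
    """Complex samples on radial spokes: ``samples[view, radial_index]``."""

    samples: np.ndarray
    angles: np.ndarray
    n_detectors: int
    detector_spacing: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.samples.shape != (self.angles.size, self.n_detectors):
            raise ValueError("samples must have shape [n_views, n_detectors]")

    @property
    def n_views(self) -> int:
        return self.samples.shape[0]

    @property
    def radial_indices(self) -> np.ndarray:
        """Signed radial sample indices; DC sits at array index ``D // 2``."""
        d = self.n_detectors
        return np.arange(d) - d // 2

    @property
    def dc_index(self) -> int:
        return self.n_detectors // 2


def projections_to_radial_kspace(sino: Sinogram) -> RadialKSpace:
    """1D Fourier transform of each parallel projection (central slice).

    The transform is phased so that the spatial origin is the isocenter
    (detector offset 0, at fractional sample ``(D-1)/2``), and shifted so
    DC lands at the central radial index.  Samples carry a factor of the
    detector spacing, approximating the continuous Fourier integral.
    """
    if sino.geometry.beam_type != "parallel":
        raise ValueError(
            "radial k-space requires parallel-beam projections; rebin fan data "
            "with rebin_fan_to_parallel first"
        )
    d = sino.geometry.n_detectors
    s = sino.geometry.detector_spacing
    m = np.arange(d) - d // 2
    # phase reference at the symmetric detector center (D-1)/2
    phase = np.exp(2j * np.pi * m * ((d - 1) / 2.0) / d)
    spectra = np.fft.fftshift(np.fft.fft(sino.values, axis=1), axes=1) * phase * s
    return RadialKSpace(spectra, sino.view_angles, d, s)


_VORONOI_CACHE: dict[tuple, np.ndarray] = {}


def voronoi_weights(kspace: RadialKSpace, use_cache: bool = True) -> np.ndarray:
    """Density-compensation weights from a 2D Voronoi tessellation.

    Each radial sample is weighted by the area of its Voronoi cell (in
    squared index units), with cells clipped to the maximum-|k| disk.  The
    duplicated DC sample is treated as one shared point whose cell area is
    split evenly across views.  Guard samples two cells beyond the k-space
    edge bound the outer cells.  For an ideal radial trajectory the interior
    weights follow the ramp ``|k| * pi / n_views``.
    """
    if kspace.n_views < 3:
        raise ValueError("Voronoi weights require at least 3 views")
    key = (
        kspace.n_views,
        kspace.n_detectors,
        round(float(kspace.angles[0]), 12),
        round(float(kspace.angles[-1]), 12),
    )
    if use_cache and key in _VORONOI_CACHE:
        return _VORONOI_CACHE[key]

    d = kspace.n_detectors
    m = kspace.radial_indices
    nonzero = m != 0
    mv = m[nonzero].astype(float)
    ct = np.cos(kspace.angles)[:, None]
    st = np.sin(kspace.angles)[:, None]
    pts_x = (mv[None, :] * ct).ravel()
    pts_y = (mv[None, :] * st).ravel()
    n_real = pts_x.size
    # guard samples beyond the edge so outer cells are bounded
    guard_r = np.array([d / 2 + 1.0, d / 2 + 2.0, -(d / 2 + 1.0), -(d / 2 + 2.0)])
    gx = (guard_r[None, :] * ct).ravel()
    gy = (guard_r[None, :] * st).ravel()
    points = np.column_stack(
        [np.concatenate([pts_x, gx, [0.0]]), np.concatenate([pts_y, gy, [0.0]])]
    )
    dc_point = points.shape[0] - 1

    # deduplicate identical coordinates (defensive; DC is already unique here)
    vor = Voronoi(points)
    areas = _region_areas(vor, n_real, dc_point)

    weights = np.zeros((kspace.n_views, d), dtype=float)
    cell = areas[:n_real].reshape(kspace.n_views, d - 1)
    weights[:, nonzero] = cell
    # clip the outermost cells to the max-|k| disk
    edge = np.abs(m[nonzero]) == d // 2
    if np.any(edge):
        r = d / 2.0
        full = (r + 0.5) ** 2 - (r - 0.5) ** 2
        clipped = r**2 - (r - 0.5) ** 2
        weights[:, nonzero] *= np.where(edge, clipped / full, 1.0)[None, :]
    # DC: one shared sample, its area split across the duplicated entries
    weights[:, kspace.dc_index] = areas[dc_point] / kspace.n_views
    if use_cache:
        _VORONOI_CACHE[key] = weights
    return weights


def _region_areas(vor: Voronoi, n_real: int, dc_point: int) -> np.ndarray:
    """Polygon areas (shoelace) of the Voronoi cells of each input point."""
    areas = np.zeros(len(vor.points))
    verts = vor.vertices
    wanted = list(range(n_real)) + [dc_point]
    for p in wanted:
        region = vor.regions[vor.point_region[p]]
        if not region or -1 in region:
            continue  # unbounded cells belong to guards only
        poly = verts[region]
        x, y = poly[:, 0], poly[:, 1]
        areas[p] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return areas


def ramp_weights(kspace: RadialKSpace) -> np.ndarray:
    """Analytic ramp density compensation for an ideal radial trajectory:
    annulus sector areas ``|k| * pi / n_views`` (DC gets the small central
    disk, shared across views)."""
    m = np.abs(kspace.radial_indices).astype(float)
    w = np.tile(m * np.pi / kspace.n_views, (kspace.n_views, 1))
    w[:, kspace.dc_index] = np.pi * 0.25 / kspace.n_views
    edge = m == kspace.n_detectors // 2
    r = kspace.n_detectors / 2.0
    w[:, edge] *= (r**2 - (r - 0.5) ** 2) / ((r + 0.5) ** 2 - (r - 0.5) ** 2)
    return w


def regrid_to_cartesian(
    kspace: RadialKSpace,
    weights: np.ndarray,
    kernel: KernelSpec = KernelSpec(),
) -> np.ndarray:
    """Convolve weighted radial samples onto an oversampled Cartesian grid.

    Returns a complex ``(os * D, os * D)`` array with DC at index
    ``os * D // 2`` along both axes.
    """
    d = kspace.n_detectors
    os_ = kernel.oversampling
    g = os_ * d
    if kernel.width > g:
        raise ValueError("kernel width exceeds the grid size")
    m = kspace.radial_indices.astype(float)
    gx = g // 2 + os_ * m[None, :] * np.cos(kspace.angles)[:, None]
    gy = g // 2 + os_ * m[None, :] * np.sin(kspace.angles)[:, None]

    # half-pixel shift so the reconstructed image is centered on the
    # ((N-1)/2, (N-1)/2) pixel convention used by the projector
    shift = np.exp(
        1j * np.pi * (m[None, :] / d) * (np.cos(kspace.angles) + np.sin(kspace.angles))[:, None]
    )
    vals = (kspace.samples * shift * weights).ravel()
    gx = gx.ravel()
    gy = gy.ravel()

    grid_re = np.zeros(g * g)
    grid_im = np.zeros(g * g)
    x0 = np.floor(gx).astype(np.int64)
    y0 = np.floor(gy).astype(np.int64)
    fx = gx - x0
    fy = gy - y0
    half = kernel.width / 2.0
    # offsets -floor(w/2) .. floor(w/2)+1 cover |o - f| <= w/2 for f in [0,1)
    lo = -int(np.floor(half))
    hi = int(np.floor(half)) + 2
    tab_u, tab_k = kernel.table()

    def kval(dist: np.ndarray) -> np.ndarray:
        return np.interp(np.abs(dist), tab_u, tab_k, right=0.0)

    kxs = {ox: kval(ox - fx) for ox in range(lo, hi)}
    vre, vim = vals.real, vals.imag
    for oy in range(lo, hi):
        ky = kval(oy - fy)
        yy = y0 + oy
        oky = (yy >= 0) & (yy < g) & (ky > 0)
        for ox in range(lo, hi):
            kx = kxs[ox]
            xx = x0 + ox
            ok = oky & (xx >= 0) & (xx < g) & (kx > 0)
            if not np.any(ok):
                continue
            w = (ky * kx)[ok]
            idx = yy[ok] * g + xx[ok]
            grid_re += np.bincount(idx, weights=w * vre[ok], minlength=g * g)
            grid_im += np.bincount(idx, weights=w * vim[ok], minlength=g * g)
    return (grid_re + 1j * grid_im).reshape(g, g)


def inverse_fft_and_deapodize(
    cartesian: np.ndarray,
    kernel: KernelSpec,
    final_size: int,
    n_detectors: int,
    detector_spacing: float,
) -> np.ndarray:
    """2D inverse FFT of the gridded k-space, deapodization and center crop.

    Returns a real ``final_size x final_size`` image in attenuation units
    (mm^-1) at the detector sampling pitch.
    """
    g = cartesian.shape[0]
    if g != kernel.oversampling * n_detectors:
        raise ValueError("grid size does not match oversampling * n_detectors")
    img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(cartesian)))
    img *= g**2 / (n_detectors * detector_spacing) ** 2
    dea = kernel.deapodization(g)
    denom = np.outer(dea, dea)
    small = np.abs(denom) < 1e-8 * np.abs(denom).max()
    denom = np.where(small, np.inf, denom)
    img = img / denom
    c = g // 2
    h0 = final_size // 2
    sl = slice(c - h0, c - h0 + final_size)
    return np.real(img[sl, sl])
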