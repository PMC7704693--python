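"""Projection geometry, parallel-beam forward projection, and fan-to-parallel rebinning.

Conventions (used throughout the package):

* the isocenter sits at pixel ``((N-1)/2, (N-1)/2)`` of an ``N x N`` image,
* detector offsets are symmetric about zero, ``t_d = (d - (D-1)/2) * detector_spacing``,
* view angles are measured counter-clockwise from the +x axis,
* a parallel projection is ``p(theta, t) = integral of mu along the line
  x cos(theta) + y sin(theta) = t`` (the Radon transform), so values are
  dimensionless line integrals of attenuation (mm^-1 times mm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProjectionGeometry",
    "Sinogram",
    "forward_project_parallel",
    "rebin_fan_to_parallel",
]


@dataclass(frozen=True)
class ProjectionGeometry:
    """Acquisition geometry for a 2D CT scan.

    Parameters
    ----------
    beam_type:
        ``"parallel"`` or ``"fan"``.
    n_detectors:
        Number of detector channels per view.
    detector_spacing:
        Detector sampling interval in mm.  For fan beams this is the spacing
        on the (curved, equiangular) detector arc.
    n_views_per_rotation:
        Number of views acquired over a full rotation.  Parallel-beam
        sinograms store the ``n_views_per_rotation / 2`` distinct angles that
        cover a half rotation.
    start_angle:
        Angle of the first view, radians CCW from +x.
    source_to_detector, source_to_isocenter:
        Fan-beam distances in mm; ``None`` for parallel beams.
    """

    beam_type: str
    n_detectors: int
    detector_spacing: float
    n_views_per_rotation: int
    start_angle: float = 0.0
    source_to_detector: float | None = None
    source_to_isocenter: float | None = None

    def __post_init__(self) -> None:
        if self.beam_type not in ("parallel", "fan"):
            raise ValueError(f"unknown beam_type {self.beam_type!r}")
        if self.n_detectors <= 0 or self.n_views_per_rotation <= 0:
            raise ValueError("n_detectors and n_views_per_rotation must be positive")
        if self.beam_type == "fan":
            if not self.source_to_detector or not self.source_to_isocenter:
                raise ValueError("fan geometry requires source distances")

    @property
    def n_parallel_views(self) -> int:
        """Number of distinct parallel view angles over a half rotation."""
        return self.n_views_per_rotation // 2

    @property
    def nyquist_complete(self) -> bool:
        """True iff the angular sampling meets the radial Nyquist criterion,
        ``N_views_per_rotation >= (pi/2) N_detectors``."""
        return self.n_views_per_rotation >= np.pi / 2 * self.n_detectors

    @property
    def detector_offsets(self) -> np.ndarray:
        """Signed detector coordinates in mm, symmetric about the center ray."""
        d = np.arange(self.n_detectors, dtype=float)
        return (d - (self.n_detectors - 1) / 2.0) * self.detector_spacing


@dataclass
class Sinogram:
    """A stack of projections: ``values[view, detector]`` are line integrals."""

    values: np.ndarray
    geometry: ProjectionGeometry
    view_angles: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("sinogram values must be 2D [view, detector]")
        if self.values.shape[1] != self.geometry.n_detectors:
            raise ValueError(
                f"sinogram has {self.values.shape[1]} detector samples, geometry "
                f"declares {self.geometry.n_detectors}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram contains non-finite values")
        if self.view_angles is None:
            self.view_angles = default_view_angles(self.geometry)
        self.view_angles = np.asarray(self.view_angles, dtype=float)
        if self.view_angles.shape[0] != self.values.shape[0]:
            raise ValueError("view_angles length does not match number of views")

    @property
    def n_views(self) -> int:
        return self.values.shape[0]


def default_view_angles(geometry: ProjectionGeometry) -> np.ndarray:
    """Evenly spaced view angles: a half rotation (no duplication) for
    parallel beams, a full rotation for fan beams."""
    if geometry.beam_type == "parallel":
        n = geometry.n_parallel_views
        return geometry.start_angle + np.arange(n) * (np.pi / n)
    n = geometry.n_views_per_rotation
    return geometry.start_angle + np.arange(n) * (2 * np.pi / n)


def forward_project_parallel(
    image: np.ndarray,
    pixel_spacing: float,
    geometry: ProjectionGeometry,
    view_angles: np.ndarray | None = None,
) -> Sinogram:
    """Forward project an attenuation map to a parallel-beam sinogram.

    Uses a Joseph-style driven-axis projector: for each view the line
    integral is accumulated by stepping along the image axis most aligned
    with the ray and interpolating linearly along the other axis, with the
    path-length factor ``pixel_spacing / max(|cos|, |sin|)``.

    Parameters
    ----------
    image:
        Square 2D attenuation map in mm^-1.
    pixel_spacing:
        Pixel size in mm.
    geometry:
        Parallel-beam geometry; ``n_parallel_views`` angles over 180 degrees
        are simulated unless ``view_angles`` is given.
    """
    image = np.asarray(image, dtype=float)
    if geometry.beam_type != "parallel":
        raise ValueError("forward_project_parallel requires parallel geometry")
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square (2D, equal sides)")
    if np.any(image < 0):
        warnings.warn("attenuation map contains negative values", stacklevel=2)

    if view_angles is None:
        view_angles = default_view_angles(geometry)
    view_angles = np.asarray(view_angles, dtype=float)

    n = image.shape[0]
    c = (n - 1) / 2.0  # isocenter, pixel units
    # detector offsets in pixel units
    t = geometry.detector_offsets / pixel_spacing

    sino = np.empty((view_angles.size, geometry.n_detectors), dtype=float)
    rows = np.arange(n, dtype=float)
    for v, theta in enumerate(view_angles):
        ct, st = np.cos(theta), np.sin(theta)
        if abs(ct) >= abs(st):
            # drive along y (image rows); solve x from x ct + y st = t
            y = rows - c  # [n]
            x = (t[:, None] - y[None, :] * st) / ct + c  # [D, n]
            sino[v] = _interp_rows(image, x) * (pixel_spacing / abs(ct))
        else:
            x = rows - c
            y = (t[:, None] - x[None, :] * ct) / st + c  # [D, n]
            sino[v] = _interp_cols(image, y) * (pixel_spacing / abs(st))
    return Sinogram(sino, geometry, view_angles)


def _interp_rows(image: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Sum over rows of linear interpolation along axis 1 (columns).

    ``x[d, j]`` is the fractional column coordinate where ray ``d`` crosses
    image row ``j``.  Out-of-bounds samples contribute zero.
    """
    n = image.shape[1]
    i0 = np.floor(x).astype(np.int64)
    f = x - i0
    valid0 = (i0 >= 0) & (i0 < n)
    valid1 = (i0 + 1 >= 0) & (i0 + 1 < n)
    i0c = np.clip(i0, 0, n - 1)
    i1c = np.clip(i0 + 1, 0, n - 1)
    j = np.broadcast_to(np.arange(image.shape[0]), x.shape)
    a = image[j, i0c] * np.where(valid0, 1.0 - f, 0.0)
    b = image[j, i1c] * np.where(valid1, f, 0.0)
    return (a + b).sum(axis=1)


def _interp_cols(image: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sum over columns of linear interpolation along axis 0 (rows)."""
    return _interp_rows(image.T, y)


def rebin_fan_to_parallel(
    fan_sino: Sinogram, target_geometry: ProjectionGeometry
) -> Sinogram:
    """Rebin a full-rotation equiangular fan-beam sinogram to parallel beams.

    Each parallel ray (phi, t) corresponds to the fan ray at fan angle
    ``gamma = asin(t / SID)`` fired from tube angle ``beta = phi - gamma``;
    samples are interpolated bilinearly in (beta, gamma).  The output covers
    180 degrees with half as many views as the fan input, relying on the
    angular redundancy of a full rotation.
    """
    geom = fan_sino.geometry
    if geom.beam_type != "fan":
        raise ValueError("rebin_fan_to_parallel requires fan-beam input")
    if target_geometry.beam_type != "parallel":
        raise ValueError("target geometry must be parallel")
    span = fan_sino.view_angles.max() - fan_sino.view_angles.min()
    n_in = fan_sino.n_views
    if span < 2 * np.pi * (1 - 1.5 / n_in):
        raise ValueError(
            "fan data must cover a full rotation (angular redundancy is needed)"
        )
    sid = geom.source_to_isocenter
    # fan angle per detector channel on the equiangular arc
    gamma = geom.detector_offsets / geom.source_to_detector

    out_angles = default_view_angles(target_geometry)
    t_out = target_geometry.detector_offsets
    with np.errstate(invalid="ignore"):
        gamma_out = np.arcsin(np.clip(t_out / sid, -1.0, 1.0))

    beta0 = fan_sino.view_angles[0]
    dbeta = fan_sino.view_angles[1] - fan_sino.view_angles[0]
    dgamma = gamma[1] - gamma[0]

    values = np.empty((out_angles.size, t_out.size), dtype=float)
    for v, phi in enumerate(out_angles):
        beta = phi - gamma_out  # [D_out]
        bi = np.mod(beta - beta0, 2 * np.pi) / dbeta
        gi = (gamma_out - gamma[0]) / dgamma
        values[v] = _bilinear_periodic(fan_sino.values, bi, gi)
    values[:, np.abs(t_out) >= sid] = 0.0
    return Sinogram(values, target_geometry, out_angles)


def _bilinear_periodic(grid: np.ndarray, bi: np.ndarray, gi: np.ndarray) -> np.ndarray:
    """Bilinear interpolation, periodic in axis 0 (tube angle), clamped in axis 1."""
    nb, ng = grid.shape
    b0 = np.floor(bi).astype(np.int64)
    g0 = np.floor(gi).astype(np.int64)
    fb = bi - b0
    fg = gi - g0
    b0 = np.mod(b0, nb)
    b1 = np.mod(b0 + 1, nb)
    g0 = np.clip(g0, 0, ng - 1)
    g1 = np.clip(g0 + 1, 0, ng - 1)
    return (
        grid[b0, g0] * (1 - fb) * (1 - fg)
        + grid[b1, g0] * fb * (1 - fg)
        + grid[b0, g1] * (1 - fb) * fg
        + grid[b1, g1] * fb * fg
    )
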