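"""End-to-end reconstruction chains.

``regrid_reconstruct`` is the plain (no view sharing) gridding
reconstruction of a single sinogram; ``reconstruct_kwia_series`` applies
the full KWIA chain to a dynamic sinogram series: per-frame radial FFT,
ring-wise temporal averaging, Voronoi density compensation, Kaiser-Bessel
regridding, inverse FFT and deapodization.  With a single ring KWIA reduces
exactly to plain regridding.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .containers import DynamicSeries
from .geometry import Sinogram
from .kspace import (
    KernelSpec,
    RadialKSpace,
    inverse_fft_and_deapodize,
    projections_to_radial_kspace,
    regrid_to_cartesian,
    voronoi_weights,
)
from .rings import RingSpec, kwia_combine

__all__ = ["regrid_reconstruct", "regrid_reconstruct_series", "reconstruct_kwia_series"]


def _recon_one(
    kspace: RadialKSpace,
    weights: np.ndarray,
    kernel: KernelSpec,
    final_size: int,
) -> np.ndarray:
    grid = regrid_to_cartesian(kspace, weights, kernel)
    return inverse_fft_and_deapodize(
        grid, kernel, final_size, kspace.n_detectors, kspace.detector_spacing
    )


def regrid_reconstruct(
    sino: Sinogram,
    kernel: KernelSpec = KernelSpec(),
    final_size: int | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Plain regridding reconstruction of one parallel-beam sinogram."""
    ks = projections_to_radial_kspace(sino)
    if weights is None:
        weights = voronoi_weights(ks)
    if final_size is None:
        final_size = sino.geometry.n_detectors
    return _recon_one(ks, weights, kernel, final_size)


def regrid_reconstruct_series(
    sinos: Sequence[Sinogram],
    kernel: KernelSpec = KernelSpec(),
    final_size: int | None = None,
) -> DynamicSeries:
    """Plain regridding reconstruction of every frame (no view sharing)."""
    if not sinos:
        raise ValueError("empty sinogram series")
    ks0 = projections_to_radial_kspace(sinos[0])
    weights = voronoi_weights(ks0)
    if final_size is None:
        final_size = sinos[0].geometry.n_detectors
    frames = [_recon_one(ks0, weights, kernel, final_size)]
    for sino in sinos[1:]:
        frames.append(
            _recon_one(projections_to_radial_kspace(sino), weights, kernel, final_size)
        )
    return DynamicSeries(np.stack(frames), sinos[0].geometry.detector_spacing, 1.0)


def reconstruct_kwia_series(
    sinos: Sequence[Sinogram],
    rings: RingSpec,
    kernel: KernelSpec = KernelSpec(),
    final_size: int | None = None,
    frame_interval: float = 1.0,
    frame_indices: Sequence[int] | None = None,
) -> DynamicSeries:
    """KWIA reconstruction of a dynamic parallel-beam sinogram series.

    Parameters
    ----------
    sinos:
        Per-frame sinograms sharing one geometry; the series must be at
        least as long as the largest averaging window.
    rings:
        Ring radii and temporal window sizes.
    frame_indices:
        Optional subset of frames to reconstruct (all by default); the
        temporal averaging always draws on the full series.
    """
    n = len(sinos)
    if n < rings.max_window:
        raise ValueError(
            f"series of {n} frames is shorter than the largest averaging window "
            f"({rings.max_window})"
        )
    kspaces = [projections_to_radial_kspace(s) for s in sinos]
    weights = voronoi_weights(kspaces[0])
    if final_size is None:
        final_size = sinos[0].geometry.n_detectors
    if frame_indices is None:
        frame_indices = range(n)
    frames = []
    for i in frame_indices:
        combined = kwia_combine(kspaces, rings, i)
        frames.append(_recon_one(combined, weights, kernel, final_size))
    return DynamicSeries(
        np.stack(frames), sinos[0].geometry.detector_spacing, frame_interval
    )
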