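"""In-memory containers and on-disk formats.

Sinograms travel in a versioned HDF5 container (dataset ``sinogram`` indexed
[view, detector], geometry fields as root attributes); image time series are
4D NIfTI with pixel spacing and frame interval carried in the header; curves
and scalar metrics are plain CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

SINOGRAM_SCHEMA_VERSION = 1

__all__ = [
    "DynamicSeries",
    "save_sinogram",
    "load_sinogram",
    "save_series",
    "load_series",
    "save_curve",
    "load_curve",
]


@dataclass
class DynamicSeries:
    """A time-ordered stack of reconstructed (or rendered) frames.

    ``frames`` has shape [n_frames, ny, nx]; ``pixel_spacing`` is in mm and
    ``frame_interval`` in seconds.
    """

    frames: np.ndarray
    pixel_spacing: float
    frame_interval: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be 3D [frame, y, x]")
        if self.frame_interval <= 0 or self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def save_sinogram(path: str | Path, sino) -> None:
    """Write a sinogram (or a [frame, view, detector] stack) to HDF5."""
    from .geometry import Sinogram  # local import to avoid a cycle

    if not isinstance(sino, Sinogram):
        raise TypeError("expected a Sinogram")
    g = sino.geometry
    with h5py.File(path, "w") as f:
        f.create_dataset("sinogram", data=sino.values)
        f.create_dataset("view_angles", data=sino.view_angles)
        f.attrs["schema_version"] = SINOGRAM_SCHEMA_VERSION
        f.attrs["beam_type"] = g.beam_type
        f.attrs["n_detectors"] = g.n_detectors
        f.attrs["detector_spacing"] = g.detector_spacing
        f.attrs["n_views_per_rotation"] = g.n_views_per_rotation
        f.attrs["start_angle"] = g.start_angle
        if g.source_to_detector is not None:
            f.attrs["source_to_detector"] = g.source_to_detector
            f.attrs["source_to_isocenter"] = g.source_to_isocenter


def load_sinogram(path: str | Path):
    """Read a sinogram container written by :func:`save_sinogram`."""
    from .geometry import ProjectionGeometry, Sinogram

    with h5py.File(path, "r") as f:
        if "schema_version" not in f.attrs:
            raise ValueError(f"{path}: not a sinogram container (missing schema_version)")
        version = int(f.attrs["schema_version"])
        if version != SINOGRAM_SCHEMA_VERSION:
            raise ValueError(
                f"{path}: unsupported sinogram schema version {version} "
                f"(expected {SINOGRAM_SCHEMA_VERSION})"
            )
        required = ("beam_type", "n_detectors", "detector_spacing", "n_views_per_rotation")
        missing = [k for k in required if k not in f.attrs]
        if missing:
            raise ValueError(f"{path}: malformed container, missing attributes {missing}")
        geom = ProjectionGeometry(
            beam_type=str(f.attrs["beam_type"]),
            n_detectors=int(f.attrs["n_detectors"]),
            detector_spacing=float(f.attrs["detector_spacing"]),
            n_views_per_rotation=int(f.attrs["n_views_per_rotation"]),
            start_angle=float(f.attrs.get("start_angle", 0.0)),
            source_to_detector=(
                float(f.attrs["source_to_detector"]) if "source_to_detector" in f.attrs else None
            ),
            source_to_isocenter=(
                float(f.attrs["source_to_isocenter"]) if "source_to_isocenter" in f.attrs else None
            ),
        )
        values = f["sinogram"][()]
        angles = f["view_angles"][()] if "view_angles" in f else None
    return Sinogram(values, geom, angles)


def save_series(path: str | Path, series: DynamicSeries) -> None:
    """Write a dynamic series as 4D NIfTI (x, y, z=1, t)."""
    data = np.transpose(series.frames, (2, 1, 0))[:, :, np.newaxis, :]
    affine = np.diag([series.pixel_spacing, series.pixel_spacing, 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms(
        (series.pixel_spacing, series.pixel_spacing, 1.0, series.frame_interval)
    )
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_series(path: str | Path) -> DynamicSeries:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series")
    frames = np.transpose(data[:, :, 0, :], (2, 1, 0)).astype(float)
    return DynamicSeries(frames, float(zooms[0]), float(zooms[3]))


def save_curve(path: str | Path, values: np.ndarray, frame_interval: float) -> None:
    """Write a time curve as CSV with columns ``frame,time_s,value``."""
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        {
            "frame": np.arange(values.size),
            "time_s": np.arange(values.size) * frame_interval,
            "value": values,
        }
    )
    df.to_csv(path, index=False)


def load_curve(path: str | Path) -> tuple[np.ndarray, float]:
    df = pd.read_csv(path)
    dt = float(df["time_s"].iloc[1] - df["time_s"].iloc[0]) if len(df) > 1 else 1.0
    return df["value"].to_numpy(), dt
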