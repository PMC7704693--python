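"""Image-quality metrics: ROI SNR, two-ROI CNR, Bland-Altman agreement.

SNR is the ratio of the ROI mean to the ROI standard deviation (sample SD,
denominator n-1) measured in a relatively uniform region; CNR is the mean
difference between two ROIs over the square root of the sum of their
variances.  Note the asymmetry: CNR is invariant to adding a constant to
the image, SNR is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ROI", "roi_snr", "roi_cnr", "bland_altman", "UndefinedMetricError"]


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined (e.g. zero variance in a uniform ROI)."""


@dataclass(frozen=True)
class ROI:
    """A circular ROI (pixel units) or an explicit boolean mask.

    For circles a pixel belongs to the ROI iff its center lies inside the
    radius.  ``center`` is (row, col).
    """

    shape: str = "circle"
    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 0.0
    mask_array: np.ndarray | None = None

    def mask(self, image_shape: tuple[int, int]) -> np.ndarray:
        if self.shape == "mask":
            if self.mask_array is None:
                raise ValueError("mask ROI requires mask_array")
            m = np.asarray(self.mask_array, dtype=bool)
            if m.shape != tuple(image_shape):
                raise ValueError("mask shape does not match image shape")
            return m
        if self.shape != "circle":
            raise ValueError(f"unknown ROI shape {self.shape!r}")
        r, c = np.ogrid[: image_shape[0], : image_shape[1]]
        return (r - self.center[0]) ** 2 + (c - self.center[1]) ** 2 <= self.radius**2

    @classmethod
    def circle_mm(
        cls,
        center_mm: tuple[float, float],
        radius_mm: float,
        image_size: int,
        pixel_spacing: float,
    ) -> "ROI":
        """Circle defined in mm about the isocenter, converted to pixels.

        ``center_mm`` is (x, y) with x along columns and y along rows.
        """
        c = (image_size - 1) / 2.0
        row = c + center_mm[1] / pixel_spacing
        col = c + center_mm[0] / pixel_spacing
        return cls("circle", (row, col), radius_mm / pixel_spacing)


def _roi_pixels(image: np.ndarray, roi: ROI) -> np.ndarray:
    px = np.asarray(image)[roi.mask(np.asarray(image).shape)]
    if px.size < 2:
        raise ValueError("ROI must contain at least 2 pixels")
    return px


def roi_snr(image: np.ndarray, roi: ROI, noise_image: np.ndarray | None = None) -> float:
    """ROI mean over ROI standard deviation (ddof=1).

    If ``noise_image`` is given (e.g. the difference between a noisy and a
    noiseless reconstruction), the SD is measured on it instead of on
    ``image``, removing any deterministic texture from the noise estimate.
    """
    px = _roi_pixels(image, roi)
    noise_px = px if noise_image is None else _roi_pixels(noise_image, roi)
    sd = noise_px.std(ddof=1)
    if sd == 0:
        raise UndefinedMetricError("SNR undefined: uniform region (zero SD)")
    return float(px.mean() / sd)


def roi_noise_sd(image: np.ndarray, roi: ROI) -> float:
    """Sample SD (ddof=1) inside the ROI."""
    return float(_roi_pixels(image, roi).std(ddof=1))


def roi_cnr(image: np.ndarray, roi1: ROI, roi2: ROI) -> float:
    """Contrast-to-noise ratio ``(mean1 - mean2) / sqrt(var1 + var2)``."""
    p1 = _roi_pixels(image, roi1)
    p2 = _roi_pixels(image, roi2)
    denom = np.sqrt(p1.var(ddof=1) + p2.var(ddof=1))
    if denom == 0:
        raise UndefinedMetricError("CNR undefined: both ROIs have zero variance")
    return float((p1.mean() - p2.mean()) / denom)


def bland_altman(values_a: np.ndarray, values_b: np.ndarray) -> dict:
    """Mean difference and 95% limits of agreement for paired measurements.

    Returns ``{"bias", "loa_low", "loa_high", "sd"}`` with the limits at
    bias +/- 1.96 SD of the pairwise differences.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired value arrays must have equal shape")
    if a.size < 2:
        raise ValueError("Bland-Altman requires at least 2 pairs")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "sd": sd,
    }
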