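"""Poisson low-dose simulation for CT sinograms.

The photon model is deliberately minimal, following two standard
simplifications: detected counts are Poisson-distributed (the compound
Poisson detector process is well approximated by a Poisson), and electronic
(Gaussian) read-out noise is ignored.  Tube-current reduction scales the
emitted photon number proportionally.

Two entry points cover the two simulation situations:

* :func:`counts_from_line_integrals` draws counts from a *noiseless*
  sinogram — ``N_d ~ Poisson(f N_e exp(-l))`` with dose fraction ``f``;
* :func:`inject_dose_reduction` lowers the dose of an *already noisy*
  full-dose count sinogram by adding an independent zero-mean
  Poisson-derived term so that the output has both the mean and the
  variance of a genuine reduced-dose acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Sinogram

__all__ = [
    "DoseConfig",
    "theoretical_snr",
    "counts_from_line_integrals",
    "inject_dose_reduction",
    "line_integrals_from_counts",
]

#: Clinical-equivalent full-dose emitted photons per detector per view.
DEFAULT_N_EMITTED = 4.8e6

_MAX_MEAN = 1e12  # guard against overflow for strongly negative line integrals


@dataclass(frozen=True)
class DoseConfig:
    """Dose settings: emitted photons ``n_emitted`` (N_e), the tube-current
    fraction ``dose_fraction`` in (0, 1], and the RNG seed."""

    n_emitted: float = DEFAULT_N_EMITTED
    dose_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_emitted <= 0:
            raise ValueError("n_emitted must be positive")
        if not 0 < self.dose_fraction <= 1:
            raise ValueError("dose_fraction must be in (0, 1]")


def theoretical_snr(n_emitted: float, line_integral: float) -> float:
    """Theoretical detector SNR ``sqrt(N_e exp(-l))`` for a Poisson detector.

    Halving the emitted photons multiplies the SNR by ``1/sqrt(2)``
    (70.7%), quartering by 0.5 — the square-root dose law that the
    reconstructed-image measurements are checked against.
    """
    if n_emitted < 0 or line_integral < 0:
        raise ValueError("inputs must be non-negative")
    return float(np.sqrt(n_emitted * np.exp(-line_integral)))


def counts_from_line_integrals(sino: Sinogram, dose: DoseConfig) -> np.ndarray:
    """Draw a Poisson count sinogram from noiseless line integrals.

    Each detector sample is drawn independently as
    ``Poisson(dose_fraction * N_e * exp(-l))``; reproducible for a fixed
    seed.  Returns a counts array with the sinogram's shape.
    """
    mean = dose.dose_fraction * dose.n_emitted * np.exp(-sino.values)
    if np.any(mean > _MAX_MEAN):
        raise ValueError(
            "Poisson mean overflow: line integrals are too negative for the "
            "requested photon count"
        )
    rng = np.random.default_rng(dose.seed)
    return rng.poisson(mean).astype(np.int64)


def inject_dose_reduction(
    counts_full: np.ndarray,
    n_emitted_full: float,
    dose_fraction: float,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a reduced-dose acquisition from full-dose counts.

    The output is ``f * counts_full + P0`` where ``P0`` is a zero-mean
    Poisson-derived term with variance ``(f - f^2) * N_e * exp(-l_hat)``
    and ``l_hat`` is estimated from the observed full-dose counts.  The
    result then has mean and variance both equal to
    ``f * N_e * exp(-l)`` — the statistics of a genuine scan at dose
    fraction ``f``.  ``dose_fraction = 1`` returns the input unchanged.
    """
    counts_full = np.asarray(counts_full)
    if np.any(counts_full < 0):
        raise ValueError("counts must be non-negative")
    if dose_fraction > 1:
        raise ValueError("dose_fraction must be <= 1")
    if not 0 < dose_fraction:
        raise ValueError("dose_fraction must be positive")
    if dose_fraction == 1.0:
        return counts_full.astype(float)
    # N_e exp(-l_hat) estimated from the observed counts themselves
    variance = (dose_fraction - dose_fraction**2) * counts_full.astype(float)
    rng = np.random.default_rng(seed)
    zero_mean = rng.poisson(variance) - variance
    return dose_fraction * counts_full + zero_mean


def line_integrals_from_counts(
    counts: np.ndarray, n_emitted: float, sino_template: Sinogram | None = None
):
    """Log-convert counts back to attenuation line integrals.

    ``l = -ln(max(counts, 1) / N_e)``; counts are floored at one photon to
    guard against photon starvation in the log.  If ``sino_template`` is
    given, a :class:`~kwia.geometry.Sinogram` with its geometry is returned,
    otherwise the raw array.
    """
    if n_emitted <= 0:
        raise ValueError("n_emitted must be positive")
    counts = np.maximum(np.asarray(counts, dtype=float), 1.0)
    values = -np.log(counts / n_emitted)
    if sino_template is not None:
        return Sinogram(values, sino_template.geometry, sino_template.view_angles)
    return values
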