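"""Spectral calibration against a reflectance standard, and probe leak QC.

Calibration removes the lamp spectrum and detector response from a raw
tissue measurement R(lambda) using a calibration pair — a spectrum C(lambda)
of a 99% reflectance standard and a dark frame:

    M(lambda) = (R - dark) / (C - dark).

The leak quality-control check compares counts at an anchor wavelength
(650 nm) with the coupled probe facing a black target (R1, pure leak light)
against counts on tissue (R2): the tissue-signal-to-leak ratio
(R2 - R1)/R1 must reach 60:1 for a probe to pass manufacturing QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "RawSpectrum",
    "CalibrationPair",
    "CalibratedSpectrum",
    "CalibrationError",
    "calibrate",
    "leak_snr",
    "LEAK_SNR_THRESHOLD",
]

#: Manufacturing QC threshold on the tissue-signal-to-leak ratio.
LEAK_SNR_THRESHOLD = 60.0

#: |M| below this after dark subtraction is clipped to zero (shot noise near dark).
_NEGATIVE_CLIP = 1e-6


class CalibrationError(ValueError):
    """Raised when a calibration pair cannot normalize a measurement."""


@dataclass(frozen=True)
class RawSpectrum:
    """Counts vs wavelength at one timestamp, in instrument space."""

    wavelength_nm: NDArray[np.float64]
    counts: NDArray[np.float64]
    integration_time_ms: float = 1000.0
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        if len(self.wavelength_nm) != len(self.counts):
            raise ValueError("wavelength and counts lengths differ")
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("counts must be nonnegative")
        if self.integration_time_ms <= 0:
            raise ValueError("integration time must be positive")


@dataclass(frozen=True)
class CalibrationPair:
    """Reference (99% standard) and dark spectra for one session."""

    reference: RawSpectrum
    dark: RawSpectrum

    def __post_init__(self) -> None:
        if not np.array_equal(self.reference.wavelength_nm, self.dark.wavelength_nm):
            raise ValueError("reference and dark frames use different wavelength grids")


@dataclass(frozen=True)
class CalibratedSpectrum:
    """Dimensionless reflectance-normalized measurement M(lambda)."""

    wavelength_nm: NDArray[np.float64]
    m: NDArray[np.float64]
    timestamp_s: float = 0.0

    def window(self, lo_nm: float, hi_nm: float) -> "CalibratedSpectrum":
        """Restrict to wavelengths in the closed interval [lo, hi] nm."""
        sel = (self.wavelength_nm >= lo_nm) & (self.wavelength_nm <= hi_nm)
        return CalibratedSpectrum(self.wavelength_nm[sel], self.m[sel], self.timestamp_s)


def calibrate(raw: RawSpectrum, cal: CalibrationPair) -> CalibratedSpectrum:
    """Normalize a raw tissue spectrum: M = (R - dark)/(C - dark).

    Lamp spectrum and detector sensitivity cancel in the ratio. Raises
    :class:`CalibrationError` where the reference does not exceed the dark
    frame (no usable lamp signal). Tiny negative values of M from shot noise
    near the dark level are clipped to zero.
    """
    if not np.array_equal(raw.wavelength_nm, cal.reference.wavelength_nm):
        raise ValueError("raw spectrum and calibration pair use different grids")
    denom = cal.reference.counts - cal.dark.counts
    if np.any(denom <= 0):
        bad = raw.wavelength_nm[denom <= 0]
        raise CalibrationError(
            f"reference does not exceed dark at {bad.size} wavelengths "
            f"(first: {bad[0]:g} nm); calibration pair is invalid"
        )
    m = (raw.counts - cal.dark.counts) / denom
    m = np.where((m < 0) & (np.abs(m) < _NEGATIVE_CLIP), 0.0, m)
    return CalibratedSpectrum(raw.wavelength_nm.copy(), m, raw.timestamp_s)


def leak_snr(r1_counts: float, r2_counts: float,
             threshold: float = LEAK_SNR_THRESHOLD) -> Tuple[float, bool]:
    """Tissue-signal-to-leak ratio (R2 - R1)/R1 and its pass/fail flag.

    ``r1_counts`` are dark-subtracted counts at the anchor wavelength with the
    coupled probe on a black target (pure leak light); ``r2_counts`` the same
    on tissue. A ratio of at least ``threshold`` (default 60) passes: leak
    light then perturbs the fitted blood volume fraction by at most ~1/60.
    """
    if r1_counts <= 0:
        raise ValueError("leak counts R1 must be positive")
    if r2_counts < 0:
        raise ValueError("tissue counts R2 must be nonnegative")
    ratio = (r2_counts - r1_counts) / r1_counts
    return ratio, ratio >= threshold
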