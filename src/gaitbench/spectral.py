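"""Periodogram power-spectral-density estimation and peak features.

The PSD of the denoised (but unfiltered, i.e. still 200 Hz) acceleration and
gyroscope magnitudes carries the walking rhythm: the gyroscope peaks at the
stride frequency, the acceleration usually at its second harmonic (the step
frequency).  The two peak magnitudes in dB are used directly as features, and
the peak frequencies provide the rough per-step interval that seeds valley
detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

from .preprocess import ProcessedSignal

__all__ = ["PSDEstimate", "periodogram_psd", "psd_peak_features"]

_POWER_FLOOR = 1e-300  # keeps log10 finite on (numerically) empty bins


@dataclass
class PSDEstimate:
    """One-sided periodogram with its non-DC peak."""

    freqs: np.ndarray  # Hz, 0 .. Nyquist
    power_db: np.ndarray  # 10 log10(PSD)
    peak_freq: float  # Hz, argmax over non-DC bins
    peak_power_db: float
    source: str  # "accel" | "gyro"

    @property
    def bin_width(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def periodogram_psd(sig: ProcessedSignal, window: str = "boxcar") -> PSDEstimate:
    """Plain (rectangular-window) periodogram of the mean-removed signal.

    The mean is removed before the transform and the DC bin is excluded from
    the peak search — the gravity offset would otherwise dominate.  A
    constant signal has no spectral peak and is rejected.
    """
    x = np.asarray(sig.samples, dtype=float)
    if len(x) < 16:
        raise ValueError(f"PSD estimation needs >= 16 samples, got {len(x)}")
    x = x - x.mean()
    freqs, pxx = periodogram(x, fs=sig.sample_rate, window=window, detrend=False)
    nondc = pxx[1:]
    scale = float(np.max(np.abs(sig.samples))) or 1.0
    if np.max(nondc) <= (1e-14 * scale) ** 2:
        raise ValueError("no spectral peak: signal is constant")
    power_db = 10.0 * np.log10(np.maximum(pxx, _POWER_FLOOR))
    ipk = 1 + int(np.argmax(nondc))
    return PSDEstimate(
        freqs=freqs,
        power_db=power_db,
        peak_freq=float(freqs[ipk]),
        peak_power_db=float(power_db[ipk]),
        source=sig.source,
    )


def psd_peak_features(
    accel_psd: PSDEstimate, gyro_psd: PSDEstimate
) -> tuple[float, float]:
    """The two spectral features: peak PSD magnitude (dB) of each sensor."""
    if accel_psd.source != "accel" or gyro_psd.source != "gyro":
        raise ValueError(
            "psd_peak_features expects (accel, gyro) estimates, got "
            f"({accel_psd.source!r}, {gyro_psd.source!r})"
        )
    return accel_psd.peak_power_db, gyro_psd.peak_power_db
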