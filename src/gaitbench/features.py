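"""Stride-valley detection and the five spatio-temporal/spectral gait features.

A foot contact shows up in the acceleration magnitude as a spike followed by
a valley; strides are delimited by consecutive valleys of the instrumented
leg.  Detection seeds an expected per-step interval from the PSD peaks of
both sensors, then walks through the filtered 12.5 Hz acceleration magnitude
valley by valley, taking the argmin inside a small search interval around
each predicted location.

From the valley array V (seconds) the features are::

    C_d[k] = V[k+1] - V[k]          stride (cycle) durations
    mean cycle duration = mean(C_d)
    cycle regularity    = std(C_d)          (sample std, n-1)
    cadence R_m         = 60 * N_c / (V_l - V_f)   cycles/min, N_c = |V| - 1

plus the two PSD peak magnitudes in dB.  Feature matrices are min-max
normalized per column to [0, 1] with affine parameters kept for unseen data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocess import (
    ProcessedSignal,
    magnitude,
    mallat_lowpass,
    resample_to_common,
    wavelet_denoise,
)
from .simulate import RawTrial
from .spectral import PSDEstimate, periodogram_psd, psd_peak_features

__all__ = [
    "FEATURE_NAMES",
    "STRIDE_WINDOW_FACTOR",
    "ValleyArray",
    "GaitFeatureVector",
    "FeatureMatrix",
    "expected_step_window",
    "detect_valleys",
    "cycle_durations",
    "cycle_regularity",
    "cadence",
    "extract_features",
    "features_to_matrix",
    "normalize_features",
]

logger = logging.getLogger(__name__)

#: Canonical feature order used by every matrix and subset mask.
FEATURE_NAMES = (
    "mean_cycle_duration_s",
    "cycle_regularity_s",
    "cadence_cpm",
    "psd_peak_accel_db",
    "psd_peak_gyro_db",
)

#: Valleys are per-stride events while the PSD-derived window is per-step;
#: one stride spans two steps, hence the factor two.
STRIDE_WINDOW_FACTOR = 2.0


@dataclass
class ValleyArray:
    """Strictly increasing valley locations in seconds."""

    V: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        if np.any(np.diff(self.V) <= 0):
            raise ValueError("valley locations must be strictly increasing")

    def __len__(self) -> int:
        return len(self.V)


@dataclass
class GaitFeatureVector:
    """The five features of one trial, in Table-order."""

    mean_cycle_duration: float  # s
    cycle_regularity: float  # s
    cadence: float  # cycles/min
    psd_peak_accel: float  # dB
    psd_peak_gyro: float  # dB
    label: str = "unknown"
    trial_id: str = "trial"

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.mean_cycle_duration,
                self.cycle_regularity,
                self.cadence,
                self.psd_peak_accel,
                self.psd_peak_gyro,
            ]
        )


def expected_step_window(
    accel_psd: PSDEstimate, gyro_psd: PSDEstimate
) -> float:
    """Gross per-step interval from the two spectral peaks, in seconds.

    The acceleration peak sits at the step frequency; the gyroscope peak at
    the stride frequency, i.e. half the step frequency.  The two implied step
    intervals are averaged.
    """
    fa, fg = accel_psd.peak_freq, gyro_psd.peak_freq
    if fa <= 0 or fg <= 0:
        raise ValueError("PSD peak frequencies must be positive")
    return 0.5 * (1.0 / fa + 1.0 / (2.0 * fg))


def detect_valleys(
    sig: ProcessedSignal,
    window: float,
    search_frac: float = 0.3,
    stride_window_factor: float = STRIDE_WINDOW_FACTOR,
) -> ValleyArray:
    """Iterative rolling-window valley detection on the filtered magnitude.

    The first valley is the global minimum over the first 1.5 windows; each
    subsequent valley is the argmin within ``+- search_frac * stride_window``
    of the previous valley advanced by one stride window
    (= ``stride_window_factor * window``).  The walk stops when the search
    interval would overrun the signal.
    """
    if sig.stage != "filtered":
        raise ValueError(f"valley detection expects stage 'filtered', got {sig.stage!r}")
    if window <= 2.0 / sig.sample_rate:
        raise ValueError("window must exceed two sample periods")
    x = sig.samples
    t = sig.times
    stride_w = stride_window_factor * window

    first_mask = t <= t[0] + 1.5 * window
    if not np.any(first_mask):
        raise ValueError("insufficient strides: first-valley span is empty")
    valleys = [t[int(np.argmin(np.where(first_mask, x, np.inf)))]]

    eps = 1e-9
    while True:
        guess = valleys[-1] + stride_w
        lo, hi = guess - search_frac * stride_w, guess + search_frac * stride_w
        if hi > t[-1] + eps:
            break
        mask = (t >= lo - eps) & (t <= hi + eps)
        if not np.any(mask):
            break
        valleys.append(t[int(np.argmin(np.where(mask, x, np.inf)))])

    if len(valleys) < 2:
        raise ValueError(
            f"insufficient strides: only {len(valleys)} valley(s) detected"
        )
    return ValleyArray(np.asarray(valleys))


def cycle_durations(valleys: ValleyArray) -> np.ndarray:
    """Stride durations ``C_d[k] = V[k+1] - V[k]``."""
    if len(valleys) < 2:
        raise ValueError("cycle durations need at least 2 valleys")
    return np.diff(valleys.V)


def cycle_regularity(c_d: np.ndarray) -> float:
    """Sample standard deviation of the stride durations; -> 0 for a
    perfectly regular gait."""
    c_d = np.asarray(c_d, dtype=float)
    if len(c_d) < 2:
        raise ValueError("cycle regularity needs at least 2 cycle durations")
    return float(np.std(c_d, ddof=1))


def cadence(valleys: ValleyArray) -> float:
    """Projected strides per minute: ``60 N_c / (V_l - V_f)``."""
    if len(valleys) < 2:
        raise ValueError("cadence needs at least 2 valleys")
    span = valleys.V[-1] - valleys.V[0]
    if span <= 0:
        raise ValueError("degenerate valley span")
    n_c = len(valleys) - 1
    return 60.0 * n_c / span


def extract_features(
    trial: RawTrial,
    target_rate: float = 200.0,
    levels: int = 4,
    search_frac: float = 0.3,
    wavelet: str = "sym4",
    valley_stage: str = "filtered",
) -> GaitFeatureVector:
    """Run the full per-trial chain and assemble the five features.

    magnitude -> resample to 200 Hz -> denoise -> periodogram peaks (on the
    denoised, unfiltered signals) -> 4-level filter bank -> valley detection
    on the filtered acceleration -> cycle statistics.  ``valley_stage`` may
    be set to ``"denoised"`` to search valleys at 200 Hz instead.
    """
    stage = "magnitude"
    try:
        acc = resample_to_common(magnitude(trial, "accel"), target_rate)
        gyr = resample_to_common(magnitude(trial, "gyro"), target_rate)
        stage = "denoise"
        acc_d = wavelet_denoise(acc, levels, wavelet)
        gyr_d = wavelet_denoise(gyr, levels, wavelet)
        stage = "psd"
        acc_psd = periodogram_psd(acc_d)
        gyr_psd = periodogram_psd(gyr_d)
        pk_acc, pk_gyr = psd_peak_features(acc_psd, gyr_psd)
        stage = "filter bank"
        if valley_stage == "filtered":
            search_sig = mallat_lowpass(acc_d, levels, wavelet)
        else:
            search_sig = acc_d
        stage = "valley detection"
        window = expected_step_window(acc_psd, gyr_psd)
        valleys = detect_valleys(search_sig, window, search_frac)
        c_d = cycle_durations(valleys)
        return GaitFeatureVector(
            mean_cycle_duration=float(np.mean(c_d)),
            cycle_regularity=cycle_regularity(c_d),
            cadence=cadence(valleys),
            psd_peak_accel=pk_acc,
            psd_peak_gyro=pk_gyr,
            label=trial.label,
            trial_id=trial.trial_id,
        )
    except ValueError as exc:
        raise ValueError(f"feature extraction failed at stage '{stage}': {exc}") from exc


@dataclass
class FeatureMatrix:
    """M patterns x 5 features with optional min-max affine parameters."""

    X: np.ndarray
    labels: np.ndarray
    feature_names: tuple = FEATURE_NAMES
    trial_ids: np.ndarray | None = None
    norm_max: np.ndarray | None = None  # a_j, per column
    norm_min: np.ndarray | None = None  # b_j

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.labels):
            raise ValueError("X must be (M, N) with one label per row")

    @property
    def is_normalized(self) -> bool:
        return self.norm_max is not None

    def apply_normalization(self, X_new: np.ndarray) -> np.ndarray:
        """Apply the stored affine transform to unseen patterns."""
        if not self.is_normalized:
            raise ValueError("matrix carries no normalization parameters")
        span = self.norm_max - self.norm_min
        safe = np.where(span == 0, 1.0, span)
        out = (np.asarray(X_new, dtype=float) - self.norm_min) / safe
        return np.where(span == 0, 0.0, out)

    def inverse_normalization(self, X_norm: np.ndarray) -> np.ndarray:
        if not self.is_normalized:
            raise ValueError("matrix carries no normalization parameters")
        span = self.norm_max - self.norm_min
        return np.asarray(X_norm, dtype=float) * span + self.norm_min


def features_to_matrix(vectors: list[GaitFeatureVector]) -> FeatureMatrix:
    """Stack per-trial feature vectors into a matrix."""
    if not vectors:
        raise ValueError("no feature vectors given")
    return FeatureMatrix(
        X=np.vstack([v.as_array() for v in vectors]),
        labels=np.array([v.label for v in vectors]),
        trial_ids=np.array([v.trial_id for v in vectors]),
    )


def normalize_features(fm: FeatureMatrix) -> FeatureMatrix:
    """Min-max normalize each column independently to [0, 1].

    Heterogeneous feature scales (seconds, cycles/min, dB) rule out a global
    transform, so column j maps through ``(x - b_j) / (a_j - b_j)`` with a_j
    and b_j the column max and min.  A constant column maps to 0 with a
    warning rather than failing the whole matrix.
    """
    if fm.X.shape[0] < 2:
        raise ValueError("normalization needs at least 2 patterns")
    a = fm.X.max(axis=0)
    b = fm.X.min(axis=0)
    span = a - b
    constant = span == 0
    if np.any(constant):
        bad = [fm.feature_names[j] for j in np.flatnonzero(constant)]
        logger.warning("constant feature column(s) %s mapped to 0", bad)
    safe = np.where(constant, 1.0, span)
    Xn = np.where(constant, 0.0, (fm.X - b) / safe)
    return FeatureMatrix(
        X=Xn,
        labels=fm.labels,
        feature_names=fm.feature_names,
        trial_ids=fm.trial_ids,
        norm_max=a,
        norm_min=b,
    )
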