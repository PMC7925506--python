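"""Synthetic single-sensor IMU gait trials with full ground truth.

A smartphone strapped to the calf records tri-axial acceleration and angular
rate while a subject walks a straight path.  The clean acceleration magnitude
is a gravity baseline plus a train of biphasic foot-contact transients (a
sharp spike followed by a valley) at alternating left/right contact times; the
clean gyroscope magnitude is a raised sinusoid at the stride frequency.  Both
magnitudes receive additive zero-mean Gaussian white noise of standard
deviation ``noise_sigma`` (the classical ``s(n) = f(n) + sigma*e(n)`` model)
and are then split over fixed unit direction vectors into three channels, so
the Euclidean norm of the channels recovers the (noisy) magnitude exactly.

Because only the instrumented leg carries the sensor, its contact transients
have full amplitude while the contralateral leg's transients are scaled by
``contralateral_ratio``.  By construction the acceleration spectrum peaks at
the step frequency ``2/stride_period`` — the second harmonic of the gyroscope
fundamental ``1/stride_period`` — mirroring what is observed on real walking
data.  Pathological (hemiplegic, post-stroke) gait is emulated with a longer
stride period, larger stride-time jitter, stronger left/right asymmetry and a
weaker gyroscope excursion.

Ground truth (instrumented-leg contact times, clean and noisy magnitudes) is
stored on every synthetic trial so downstream feature recovery can be scored
against it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GaitParams",
    "RawTrial",
    "healthy_params",
    "pathological_params",
    "generate_trial",
    "generate_cohort",
    "MIN_SAMPLES",
    "GRAVITY",
    "DEFAULT_RATE_POOL",
]

#: Minimum number of samples a trial must contain for the 4-level denoiser.
MIN_SAMPLES = 128

#: Gravity baseline included in the acceleration magnitude, m/s^2.
GRAVITY = 9.81

#: Native sampling rates of the heterogeneous handsets being emulated, Hz.
DEFAULT_RATE_POOL = (50.0, 100.0, 128.0, 200.0, 256.0, 350.0)

# Fixed unit vectors used to split a scalar magnitude into three channels.
_ACCEL_DIR = np.array([1.0, 2.0, 3.0]) / np.sqrt(14.0)
_GYRO_DIR = np.array([3.0, 2.0, 1.0]) / np.sqrt(14.0)


@dataclass(frozen=True)
class GaitParams:
    """Parameters of one synthetic walking trial.

    Defaults describe a healthy adult: stride period 1.1 s (step frequency
    ~1.8 Hz), nearly symmetric left/right contacts and low stride-time jitter.
    """

    stride_period: float = 1.1  # s, full gait cycle of the instrumented leg
    stride_jitter_sd: float = 0.02  # s, i.i.d. Gaussian jitter on contact times
    step_amplitude: float = 3.0  # m/s^2, instrumented-leg contact transient
    contralateral_ratio: float = 0.9  # other leg's amplitude relative to instrumented
    gyro_amplitude: float = 1.5  # rad/s, angular-rate excursion scale
    noise_sigma: float = 0.15  # additive white-noise sd, per signal
    duration: float = 10.0  # s, in {10, 20} for the emulated protocol
    sample_rate: float = 200.0  # Hz, native handset rate in [50, 350]
    label: str = "healthy"

    def validate(self) -> None:
        if self.stride_period <= 0:
            raise ValueError("stride_period must be positive")
        if not 0.0 <= self.contralateral_ratio <= 1.0:
            raise ValueError("contralateral_ratio must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.stride_jitter_sd < 0:
            raise ValueError("stride_jitter_sd must be nonnegative")
        n = int(round(self.duration * self.sample_rate))
        if n < MIN_SAMPLES:
            raise ValueError(
                f"duration*sample_rate = {n} samples, below the "
                f"{MIN_SAMPLES}-sample minimum required by the 4-level denoiser"
            )
        if self.label not in ("healthy", "pathological"):
            raise ValueError(f"unknown label {self.label!r}")


def healthy_params(**overrides) -> GaitParams:
    """Class defaults for physiological gait."""
    return replace(GaitParams(), **overrides)


def pathological_params(**overrides) -> GaitParams:
    """Class defaults for hemiplegic (post-stroke) gait: slower, more
    irregular, more asymmetric, with weaker angular-rate dynamics."""
    base = GaitParams(
        stride_period=1.8,
        stride_jitter_sd=0.15,
        step_amplitude=3.0,
        contralateral_ratio=0.4,
        gyro_amplitude=0.8,
        label="pathological",
    )
    return replace(base, **overrides)


@dataclass
class RawTrial:
    """One recorded walking trial from a calf-mounted handset.

    ``accel`` and ``gyro`` are (n, 3) arrays in m/s^2 and rad/s.  The
    ``truth_*`` fields are populated only for synthetic trials and carry the
    generator's ground truth; they are ``None`` for trials read from disk.
    """

    time: np.ndarray  # s, strictly increasing, uniform
    accel: np.ndarray  # (n, 3) m/s^2, gravity included in the magnitude
    gyro: np.ndarray  # (n, 3) rad/s
    sample_rate: float  # Hz
    label: str
    trial_id: str = "trial"
    truth_contacts: np.ndarray | None = None  # s, instrumented-leg contacts
    truth_accel_mag: np.ndarray | None = None  # clean magnitude, pre-noise
    truth_gyro_mag: np.ndarray | None = None
    noisy_accel_mag: np.ndarray | None = None  # magnitude actually split to axes
    noisy_gyro_mag: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.time)
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("accel and gyro must be (n, 3) arrays matching time")
        if n < MIN_SAMPLES:
            raise ValueError(
                f"trial has {n} samples, below the {MIN_SAMPLES}-sample minimum"
            )
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def duration(self) -> float:
        return len(self.time) / self.sample_rate


def _contact_kernel(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Biphasic spike-then-valley transient: negated Gaussian derivative.

    Peaks at +1 one ``width`` before ``center`` and bottoms at -1 one
    ``width`` after it, so each contact contributes exactly one local valley.
    """
    u = (t - center) / width
    return -u * np.exp(0.5 * (1.0 - u * u))


def generate_trial(params: GaitParams, seed: int) -> RawTrial:
    """Simulate one trial; deterministic for fixed ``(params, seed)``."""
    params.validate()
    rng = np.random.default_rng(seed)
    n = int(round(params.duration * params.sample_rate))
    t = np.arange(n) / params.sample_rate

    T = params.stride_period
    # Kernel scale T/10: wide enough that the Gaussian-derivative spectrum
    # (~ f * exp(-2 pi^2 f^2 w^2)) decays past the step harmonic, keeping the
    # acceleration PSD peak at 2/T rather than a higher even harmonic.
    width = T / 10.0
    t_first = 0.3 * T

    accel_clean = np.full(n, GRAVITY)
    contacts = []
    k = 0
    # Alternating instrumented / contralateral contacts every half stride.
    while True:
        nominal = t_first + 0.5 * k * T
        if nominal >= params.duration - 2.0 * width:
            break
        jitter = rng.normal(0.0, params.stride_jitter_sd)
        tc = nominal + jitter
        instrumented = k % 2 == 0
        amp = params.step_amplitude if instrumented else (
            params.contralateral_ratio * params.step_amplitude
        )
        accel_clean += amp * _contact_kernel(t, tc, width)
        if instrumented:
            contacts.append(tc)
        k += 1

    # Raised sinusoid keeps the magnitude nonnegative (axis split must be
    # invertible by the Euclidean norm) while the fundamental stays at 1/T.
    gyro_clean = params.gyro_amplitude * (2.0 + np.sin(2.0 * np.pi * t / T))

    accel_noisy = accel_clean + params.noise_sigma * rng.standard_normal(n)
    gyro_noisy = gyro_clean + params.noise_sigma * rng.standard_normal(n)

    return RawTrial(
        time=t,
        accel=accel_noisy[:, None] * _ACCEL_DIR,
        gyro=gyro_noisy[:, None] * _GYRO_DIR,
        sample_rate=params.sample_rate,
        label=params.label,
        truth_contacts=np.asarray(contacts),
        truth_accel_mag=accel_clean,
        truth_gyro_mag=gyro_clean,
        noisy_accel_mag=accel_noisy,
        noisy_gyro_mag=gyro_noisy,
    )


def _duration_plan(
    n_healthy: int, n_pathological: int, duration_split: float
) -> tuple[int, int]:
    """Return (healthy 20 s count, pathological 20 s count).

    Replicates the emulated cohort's shape: 41/60 of trials last 10 s and the
    20 s group over-represents pathological subjects (12 of 19).
    """
    total = n_healthy + n_pathological
    n10 = int(round(duration_split * total))
    n20 = total - n10
    path20 = min(n_pathological, int(round(n20 * 12.0 / 19.0)))
    heal20 = min(n_healthy, n20 - path20)
    path20 = min(n_pathological, n20 - heal20)
    return heal20, path20


def generate_cohort(
    n_healthy: int = 35,
    n_pathological: int = 25,
    rate_pool: Sequence[float] = DEFAULT_RATE_POOL,
    duration_split: float = 41.0 / 60.0,
    seed: int = 0,
    separation_scale: float = 1.0,
) -> list[RawTrial]:
    """Generate a labeled cohort of synthetic trials.

    Defaults emulate a 60-trial clinical campaign: 35 healthy + 25
    pathological subjects on heterogeneous handsets (rates drawn from
    ``rate_pool``), 41 trials of 10 s and 19 of 20 s with pathological
    subjects over-represented in the longer recordings.  Per-trial parameters
    are drawn around the class defaults.

    ``separation_scale`` scales the healthy-to-pathological gap of the
    class-separating parameters (stride period, gyro amplitude, left/right
    asymmetry); 1.0 is the default regime, 2.0 a well-separated one.
    """
    if n_healthy < 0 or n_pathological < 0:
        raise ValueError("cohort counts must be nonnegative")
    rate_pool = list(rate_pool)
    if not rate_pool:
        raise ValueError("rate_pool must not be empty")
    rng = np.random.default_rng(seed)

    h, p = healthy_params(), pathological_params()
    s = separation_scale
    # Geometric scaling for the positive parameters keeps them physical
    # (a doubled gap must not push the gyro excursion under the noise floor).
    path_base = replace(
        p,
        stride_period=h.stride_period * (p.stride_period / h.stride_period) ** s,
        gyro_amplitude=h.gyro_amplitude * (p.gyro_amplitude / h.gyro_amplitude) ** s,
        contralateral_ratio=float(np.clip(
            h.contralateral_ratio + s * (p.contralateral_ratio - h.contralateral_ratio),
            0.0, 1.0,
        )),
    )

    heal20, path20 = _duration_plan(n_healthy, n_pathological, duration_split)
    plan = [("healthy", 20.0)] * heal20
    plan += [("healthy", 10.0)] * (n_healthy - heal20)
    plan += [("pathological", 20.0)] * path20
    plan += [("pathological", 10.0)] * (n_pathological - path20)
    rng.shuffle(plan)

    trials = []
    for i, (label, duration) in enumerate(plan):
        base = healthy_params() if label == "healthy" else path_base
        params = replace(
            base,
            stride_period=base.stride_period * (1.0 + 0.05 * rng.normal()),
            step_amplitude=base.step_amplitude * (1.0 + 0.10 * rng.normal()),
            gyro_amplitude=base.gyro_amplitude * abs(1.0 + 0.10 * rng.normal()),
            contralateral_ratio=float(
                np.clip(base.contralateral_ratio + 0.05 * rng.normal(), 0.0, 1.0)
            ),
            duration=duration,
            sample_rate=float(rng.choice(rate_pool)),
        )
        trial = generate_trial(params, seed=int(rng.integers(2**31)))
        trial.trial_id = f"trial_{i:03d}"
        trials.append(trial)
    return trials
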