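"""Condition one raw trial: magnitude -> 200 Hz -> denoise -> 12.5 Hz.

The tri-axial channels are collapsed to their Euclidean norm, resampled to
the common 200 Hz rate, cleaned by universal-threshold wavelet shrinkage,
and decimated through a 4-level low-pass filter bank.  The printed rates
show the 200 Hz -> 12.5 Hz contract; the variance drop shows the denoiser
at work.
"""

import numpy as np

import gaitbench as gb

trial = gb.generate_trial(gb.healthy_params(duration=20.0, noise_sigma=0.5), seed=3)

mag = gb.magnitude(trial, "accel")
res = gb.resample_to_common(mag)
den = gb.wavelet_denoise(res)
flt = gb.mallat_lowpass(den)

for sig in (mag, res, den, flt):
    print(f"{sig.stage:>9s}: {len(sig.samples):5d} samples at {sig.sample_rate:6.1f} Hz")

clean = trial.truth_accel_mag
rms_noisy = np.sqrt(np.mean((trial.noisy_accel_mag - clean) ** 2))
# compare on the native grid: this trial is generated at 200 Hz already
rms_denoised = np.sqrt(np.mean((den.samples - clean) ** 2))
print(f"\nRMS error vs clean magnitude: noisy {rms_noisy:.3f} -> denoised "
      f"{rms_denoised:.3f} m/s^2 (shrinkage removed most of the sigma=0.5 noise)")
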