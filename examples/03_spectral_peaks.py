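"""Periodogram PSD peaks: the walking rhythm in the frequency domain.

On clean data the gyroscope magnitude peaks at the stride frequency (1/T)
and the acceleration magnitude at its second harmonic, the step frequency
(2/T).  The two peak magnitudes in dB are gait features in their own right.
"""

import gaitbench as gb

params = gb.healthy_params(duration=20.0, stride_jitter_sd=0.0, noise_sigma=0.1)
trial = gb.generate_trial(params, seed=5)

acc = gb.wavelet_denoise(gb.resample_to_common(gb.magnitude(trial, "accel")))
gyr = gb.wavelet_denoise(gb.resample_to_common(gb.magnitude(trial, "gyro")))
acc_psd, gyr_psd = gb.periodogram_psd(acc), gb.periodogram_psd(gyr)

print(f"stride period: {params.stride_period} s "
      f"(stride {1/params.stride_period:.3f} Hz, step {2/params.stride_period:.3f} Hz)")
print(f"gyro  peak: {gyr_psd.peak_freq:.3f} Hz at {gyr_psd.peak_power_db:6.2f} dB")
print(f"accel peak: {acc_psd.peak_freq:.3f} Hz at {acc_psd.peak_power_db:6.2f} dB")
print(f"accel/gyro peak-frequency ratio: {acc_psd.peak_freq/gyr_psd.peak_freq:.2f} "
      "(the second-harmonic relation)")

window = gb.expected_step_window(acc_psd, gyr_psd)
print(f"expected per-step interval seeded from the peaks: {window:.3f} s")
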