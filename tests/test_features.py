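"""Valley detection, cycle statistics (stride durations, regularity,
cadence) and feature-matrix normalization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gaitbench as gb
from gaitbench.features import FEATURE_NAMES, FeatureMatrix, ValleyArray
from gaitbench.preprocess import ProcessedSignal


def _filtered(x, fs=12.5, t0=0.0):
    return ProcessedSignal(np.asarray(x, float), fs, "filtered", "accel", start_time=t0)


class _FakePSD:
    def __init__(self, peak_freq, source):
        self.peak_freq = peak_freq
        self.source = source


# ------------------------------------------------------- expected window


def test_expected_step_window_arithmetic():
    assert gb.expected_step_window(_FakePSD(2.0, "accel"), _FakePSD(1.0, "gyro")) == 0.5
    assert gb.expected_step_window(
        _FakePSD(2.0, "accel"), _FakePSD(0.8, "gyro")
    ) == pytest.approx(0.5625)
    with pytest.raises(ValueError):
        gb.expected_step_window(_FakePSD(0.0, "accel"), _FakePSD(1.0, "gyro"))


def test_expected_step_window_from_noise_free_trial():
    p = gb.healthy_params(duration=20.0, noise_sigma=0.0, stride_jitter_sd=0.0)
    trial = gb.generate_trial(p, 1)
    acc = gb.periodogram_psd(
        ProcessedSignal(trial.noisy_accel_mag, p.sample_rate, "denoised", "accel")
    )
    gyr = gb.periodogram_psd(
        ProcessedSignal(trial.noisy_gyro_mag, p.sample_rate, "denoised", "gyro")
    )
    assert gb.expected_step_window(acc, gyr) == pytest.approx(0.55, abs=0.02)


# ------------------------------------------------------- valley detection


def test_valleys_of_cosine_at_analytic_minima():
    t = np.arange(126) / 12.5
    sig = _filtered(-np.cos(2 * np.pi * t / 1.2))
    v = gb.detect_valleys(sig, window=0.6)
    expected = np.arange(len(v)) * 1.2
    assert np.max(np.abs(v.V - expected)) <= 1.0 / 12.5


def test_valleys_match_generator_truth():
    p = gb.healthy_params(duration=20.0, stride_jitter_sd=0.0)
    trial = gb.generate_trial(p, 6)
    fv = gb.extract_features(trial)
    sig = gb.mallat_lowpass(
        gb.wavelet_denoise(gb.resample_to_common(gb.magnitude(trial, "accel")))
    )
    acc_psd = gb.periodogram_psd(
        gb.wavelet_denoise(gb.resample_to_common(gb.magnitude(trial, "accel")))
    )
    gyr_psd = gb.periodogram_psd(
        gb.wavelet_denoise(gb.resample_to_common(gb.magnitude(trial, "gyro")))
    )
    window = gb.expected_step_window(acc_psd, gyr_psd)
    v = gb.detect_valleys(sig, window)
    truth = trial.truth_contacts
    assert abs(len(v) - len(truth)) <= 1
    stride_w = 2.0 * window
    matched = [np.min(np.abs(truth - t_v)) for t_v in v.V]
    assert max(matched) <= stride_w / 4.0


def test_valleys_equal_bruteforce_interval_oracle():
    """The iterative rule equals explicit argmin over each analytically
    enumerated search interval on a toy signal."""
    rng = np.random.default_rng(12)
    x = rng.standard_normal(50)
    fs, window, frac = 12.5, 0.6, 0.3
    t = np.arange(50) / fs
    sig = _filtered(x, fs)
    got = gb.detect_valleys(sig, window, search_frac=frac).V

    stride_w = 2.0 * window
    expected = [t[np.argmin(np.where(t <= 1.5 * window, x, np.inf))]]
    while True:
        guess = expected[-1] + stride_w
        lo, hi = guess - frac * stride_w, guess + frac * stride_w
        if hi > t[-1] + 1e-9:
            break
        mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
        expected.append(t[np.argmin(np.where(mask, x, np.inf))])
    assert np.allclose(got, expected, atol=1e-12)


def test_valley_errors():
    t = np.arange(40) / 12.5
    with pytest.raises(ValueError, match="insufficient strides"):
        gb.detect_valleys(_filtered(-np.cos(2 * np.pi * t / 1.2)), window=5.0)
    with pytest.raises(ValueError, match="window"):
        gb.detect_valleys(_filtered(np.ones(40)), window=0.1)
    with pytest.raises(ValueError, match="stage"):
        gb.detect_valleys(
            ProcessedSignal(np.ones(40), 12.5, "denoised", "accel"), window=0.6
        )


# ------------------------------------------------------- cycle statistics


def test_cycle_durations_examples():
    assert np.allclose(
        gb.cycle_durations(ValleyArray([0.5, 1.6, 2.6])), [1.1, 1.0]
    )
    assert np.allclose(gb.cycle_durations(ValleyArray([0, 1, 2, 3])), [1, 1, 1])
    with pytest.raises(ValueError):
        gb.cycle_durations(ValleyArray([1.0]))


@given(st.lists(st.floats(0.01, 2.0), min_size=2, max_size=30))
def test_cycle_durations_telescope(gaps):
    v = ValleyArray(np.cumsum([0.0] + gaps))
    c_d = gb.cycle_durations(v)
    assert len(c_d) == len(v) - 1
    assert np.all(c_d > 0)
    assert np.sum(c_d) == pytest.approx(v.V[-1] - v.V[0], rel=1e-12)


def test_cycle_regularity_examples_and_oracle(rng):
    assert gb.cycle_regularity([1.0, 1.0, 1.0]) == 0.0
    assert gb.cycle_regularity([1.0, 1.2]) == pytest.approx(0.2 / np.sqrt(2))
    c_d = rng.uniform(0.8, 1.4, size=17)
    # independent two-pass variance
    mean = sum(c_d) / len(c_d)
    var = sum((v - mean) ** 2 for v in c_d) / (len(c_d) - 1)
    assert gb.cycle_regularity(c_d) == pytest.approx(np.sqrt(var), rel=1e-12)
    with pytest.raises(ValueError):
        gb.cycle_regularity([1.0])


def test_cadence_examples():
    assert gb.cadence(ValleyArray([0, 1, 2, 3])) == pytest.approx(60.0)
    assert gb.cadence(ValleyArray([2.0, 3.1])) == pytest.approx(60 / 1.1)
    with pytest.raises(ValueError):
        gb.cadence(ValleyArray([1.0]))


def test_cadence_equals_inverse_mean_duration():
    """Algebraic identity: R_m = 60 / mean(C_d) for the same valley array."""
    v = ValleyArray(np.cumsum([0.0, 1.05, 1.21, 0.97, 1.13, 1.02]))
    c_d = gb.cycle_durations(v)
    assert gb.cadence(v) == pytest.approx(60.0 / np.mean(c_d), rel=1e-12)


def test_jitter_free_cadence_recovers_stride_rate():
    p = gb.healthy_params(duration=20.0, stride_jitter_sd=0.0)
    fv = gb.extract_features(gb.generate_trial(p, 8))
    assert fv.cadence == pytest.approx(60.0 / 1.1, rel=0.05)


# ------------------------------------------------------- extract_features


def test_feature_vector_has_five_entries_and_is_deterministic():
    trial = gb.generate_trial(gb.healthy_params(), 3)
    a = gb.extract_features(trial).as_array()
    b = gb.extract_features(gb.generate_trial(gb.healthy_params(), 3)).as_array()
    assert a.shape == (5,)
    assert len(FEATURE_NAMES) == 5
    assert np.array_equal(a, b)


def test_extraction_error_names_failing_stage():
    trial = gb.generate_trial(gb.healthy_params(), 3)
    trial.accel = trial.accel * 0  # constant magnitude -> PSD failure
    with pytest.raises(ValueError, match="stage 'psd'"):
        gb.extract_features(trial)


def test_class_mean_cycle_duration_tracks_stride_period(default_features):
    for label, period in (("healthy", 1.1), ("pathological", 1.8)):
        m = np.mean(
            [v.mean_cycle_duration for v in default_features if v.label == label]
        )
        assert m == pytest.approx(period, rel=0.10)


# ------------------------------------------------------- normalization


def test_normalize_column_example():
    fm = FeatureMatrix(
        X=np.array([[2.0, 1.0], [4.0, 1.5], [6.0, 3.0]]),
        labels=np.array(["a", "b", "a"]),
        feature_names=("f1", "f2"),
    )
    out = gb.normalize_features(fm)
    assert np.allclose(out.X[:, 0], [0.0, 0.5, 1.0])


def test_normalize_bounds_attained_and_idempotent(rng):
    fm = FeatureMatrix(
        X=rng.normal(size=(20, 5)), labels=np.array(["a", "b"] * 10)
    )
    out = gb.normalize_features(fm)
    assert np.allclose(out.X.min(axis=0), 0.0)
    assert np.allclose(out.X.max(axis=0), 1.0)
    again = gb.normalize_features(out)
    assert np.allclose(again.X, out.X)


def test_normalize_inverse_roundtrip(rng):
    fm = FeatureMatrix(X=rng.normal(size=(15, 5)), labels=np.array(["a"] * 15))
    out = gb.normalize_features(fm)
    assert np.allclose(out.inverse_normalization(out.X), fm.X, atol=1e-12)
    assert np.allclose(out.apply_normalization(fm.X), out.X, atol=1e-12)


def test_normalize_constant_column_maps_to_zero(caplog):
    X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
    fm = FeatureMatrix(X=X, labels=np.array(["a", "b", "a"]), feature_names=("u", "v"))
    with caplog.at_level("WARNING"):
        out = gb.normalize_features(fm)
    assert np.allclose(out.X[:, 1], 0.0)
    assert any("constant" in r.message for r in caplog.records)
    # inverse still recovers the constant
    assert np.allclose(out.inverse_normalization(out.X), X, atol=1e-12)


def test_normalize_needs_two_patterns():
    fm = FeatureMatrix(X=np.ones((1, 5)), labels=np.array(["a"]))
    with pytest.raises(ValueError):
        gb.normalize_features(fm)
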