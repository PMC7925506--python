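# Methods

## Signal model and synthetic trials

Every recorded channel is modeled as *s(n) = f(n) + σe(n)* with *e* unit
white Gaussian noise. The generator builds the two clean magnitudes
directly:

* **Acceleration magnitude** — a gravity baseline (9.81 m/s²) plus one
  biphasic transient per foot contact. The kernel is a negated Gaussian
  derivative (sharp spike, then a valley one kernel-width later), so each
  contact contributes exactly one local minimum — the "valley" the stride
  segmenter looks for. Contacts alternate between the instrumented leg
  (amplitude `step_amplitude`, default 3 m/s²) and the contralateral leg
  (scaled by `contralateral_ratio`), spaced half a stride period apart and
  perturbed by i.i.d. Gaussian jitter (`stride_jitter_sd`).
* **Gyroscope magnitude** — `gyro_amplitude · (2 + sin(2πt/T))`. The DC
  offset keeps the magnitude nonnegative, which matters because the
  three-axis channels are produced by splitting each magnitude over fixed
  unit direction vectors: the Euclidean norm then recovers the (noisy)
  magnitude exactly, making the generator invertible for testing. The
  fundamental stays at the stride frequency 1/T since the DC bin is
  excluded from all peak searches.

The kernel width is T/10. This is not cosmetic: the spectrum of a Gaussian
derivative behaves as *f·exp(−2π²f²w²)*, and for w much narrower than T/10
the envelope keeps growing past the step harmonic, pushing the acceleration
PSD peak to the fourth gyro harmonic. At w = T/10 the peak lands at the
step frequency 2/T for any left/right asymmetry, which is the
second-harmonic relation the window estimator relies on.

Class defaults (healthy → pathological): stride period 1.1 → 1.8 s, jitter
0.02 → 0.15 s, contralateral ratio 0.9 → 0.4, gyro amplitude 1.5 →
0.8 rad/s, noise σ 0.15 for both. Healthy values follow the ~1.8 Hz step
frequency of normal walking; pathological values encode the slower, more
irregular, more asymmetric hemiplegic pattern with weaker angular-rate
dynamics. Amplitude equality of the contact transients across classes is
deliberate: the class signal lives in timing, asymmetry and gyro amplitude,
mirroring the clinical observation that acceleration features discriminate
poorly.

The default cohort reproduces the emulated campaign's shape exactly: 35
healthy + 25 pathological, 41 trials of 10 s and 19 of 20 s with 12 of the
19 long recordings pathological, native rates drawn from
{50, 100, 128, 200, 256, 350} Hz. Per-trial parameters scatter around the
class defaults (5% on stride period, 10% on amplitudes). A
`separation_scale` argument widens the healthy↔pathological gap
geometrically for stride period and gyro amplitude (and linearly, clipped,
for the contralateral ratio); geometric scaling keeps a doubled gap from
pushing the gyro excursion below the noise floor. Jitter is not scaled —
it controls tracking difficulty, not class separation.

**What the generator does not emulate:** real limb kinematics (the axis
split uses fixed directions), sensor drift and bias, magnetometer data,
double-support timing structure, or the waveform variety of clinical
hemiplegia. Passing tests therefore demonstrate that the pipeline recovers
what this model embeds — not clinical accuracy levels. The headline
benchmark accuracies on synthetic cohorts (≈100%) exceed what the same
protocol yields on clinical data (80–90%) because the synthetic classes
are cleanly separated by construction.

## Preprocessing

* **Resampling** — rational-factor polyphase resampling (Kaiser β = 5
  window) to 200 Hz, with linear edge padding so the gravity offset does
  not ring at the boundaries. Signals already at 200 Hz pass through
  bit-identically. Minimum input length 32 samples (filter warm-up).
* **Denoising** — symlet-4 DWT at 4 levels, symmetric extension. Each
  detail level gets its own noise scale σ̂ = MAD/0.6745 and is
  soft-thresholded at σ̂·√(2 ln L) with L the total signal length and
  proportionality constant 1. The approximation is untouched. A zero
  threshold (noise-free level) is the identity — the natural limit, and it
  avoids 0/0 in the thresholding formula. Minimum length 2⁴·8 = 128
  samples at 4 levels, scaling as 2^levels·8.
* **Filter bank** — the low-pass/decimate-by-2 analysis branch applied 4
  times, renormalized by √2 per level so constants map to themselves.
  Symmetric extension grows each level beyond ⌈n/2⌉ samples; the output is
  trimmed back symmetrically, and the cascade's group delay is measured by
  pushing an impulse through the identical cascade (centroid of the
  response) and folded into the output's `start_time`. Without this
  calibration the ~0.26 s cumulative delay would shift every valley
  timestamp by a constant that matters at the stride-matching tolerance.

Whether denoising should run per axis or on the magnitude is genuinely
open; this package denoises the magnitude, which is also what the valley
detector consumes.

## Spectral features

Plain (rectangular-window) periodogram of the mean-removed signal — no
Welch averaging, configurable via the `window` argument. The PSD is taken
on the **denoised, unfiltered** 200 Hz signal; peaks are searched over
non-DC bins and reported as 10·log₁₀(PSD). A constant signal raises "no
spectral peak" rather than returning the floor value. The occasional
failure of the second-harmonic relation on real data has no documented
correction, so none is applied; the window estimator simply averages the
two implied step intervals.

## Valley detection and features

The per-step window is seeded from the spectra: T_step = (1/f_accel +
1/(2·f_gyro))/2. Valleys are per-stride events of the instrumented leg, so
the step window is doubled into a stride window (factor exposed as
`STRIDE_WINDOW_FACTOR`). The first valley is the global minimum over 1.5
windows from the start; each next valley is the argmin within ±0.3 stride
windows (`search_frac`, re-centering on each accepted valley so the walk
tracks jittered strides); the iteration stops when the search interval
would overrun the signal. Fewer than two valleys is an error
("insufficient strides") — on cohort runs such trials are quarantined, not
fatal.

Cycle regularity uses the sample standard deviation (n−1). The detection
runs on the filtered 12.5 Hz signal by default (`valley_stage="denoised"`
switches to 200 Hz). Cadence and mean cycle duration satisfy
R_m = 60/mean(C_d) identically when computed from the same valley array.

Normalization is fit on the full matrix before cross-validation (matching
the processing order in which normalization precedes classification); the
resulting mild leakage is documented here, and
`FeatureMatrix.apply_normalization` supports a fit-on-train-only regime
for users who want strict separation. A constant column maps to 0 with a
warning; its inverse transform still restores the constant.

## Classifiers

Scikit-learn provides SVM (RBF, C = 1, gamma = 1/(N·var), tol 1e-3) and
CART (Gini, unpruned, min leaf 1, priors implicit in the frequencies). The
rest are implemented here:

* **LDA/QDA** — Gaussian discriminants (pooled vs. per-class covariance)
  with a 1e-6 diagonal ridge. The ridge is load-bearing: cadence is almost
  exactly 60/mean-cycle-duration, so class covariances are numerically
  rank-deficient and an unregularized fit fails.
* **KNN** — K = 5 Euclidean; all points tied at the K-th distance vote.
* **Naive Bayes** — per-feature, per-class Gaussian KDE with Silverman
  bandwidths (floored for degenerate spreads), product rule in log space.
* **PNN** — class score = mean Gaussian kernel activation, spread 0.1 in
  the normalized space; argmax with ties toward the first class in sorted
  label order (this also covers the all-underflow case at tiny spreads).
* **Subtractive clustering** — Chiu's potentials with r_b = 1.5·r_a,
  accept/reject ratios 0.5/0.15 and the distance-plus-potential rule in
  the gray zone.
* **FIS** — first-order Sugeno system: one rule per cluster, Gaussian
  memberships with per-feature sd = r_a·range/√8, product firing, all
  linear consequents fit jointly by least squares on 0/1 labels (ridge
  fallback 1e-8 if the design matrix degenerates), threshold 0.5.
* **NF** — one Gaussian cluster per class (softmax over per-class
  log-memberships with trainable centers, log-widths and biases),
  initialized at class means/stds/log-frequencies and trained by Møller's
  scaled conjugate gradient on cross-entropy for at most 100 accepted
  steps. SCG accepts a step only when the loss does not increase, so the
  training history is non-increasing by construction; at 0 epochs on
  symmetric data the boundary is the midpoint hyperplane.

All classifiers assume [0,1]-normalized features and binary labels; class
order is the sorted order of the training labels.

## Cross-validation and subset search

Folds are built per class: indices shuffle under the given seed, split
into ⌈M/test_size⌉ contiguous chunks differing by at most one, with one
class's remainders placed in the earliest folds and the other's in the
latest so fold sizes stay even (on 35/25 this yields test folds of exactly
5–6 healthy and 4–5 pathological). Accuracy is pooled across folds
(micro-average; identical to the fold mean for equal folds), repeated 10
times with fresh partitions, reported as mean ± sample std (std 0 by
convention for a single repeat). The protocol described as "10-fold" in
the field source amounts to 6 iterations of 10 test patterns on 60
records; the literal description is implemented and `test_size` is
configurable.

The exhaustive search scores all 31 subsets; ties prefer fewer features,
then the lexicographically smaller mask in canonical feature order
(mean cycle duration, cycle regularity, cadence, accel PSD peak, gyro PSD
peak). On the default synthetic cohort many subsets reach 100%, so the
tie-break — not discrimination — decides the winner; this is why the
reported best subsets concentrate on a single timing feature there,
whereas on harder data the gyro PSD peak dominates.

## Problem sizes and numerical choices

Test-suite and acceptance-script sizes are the package's own choices:
ground-truth recovery uses 20 seeded 60-trial cohorts in the tests and 10
in the acceptance script; the subset-occurrence Monte-Carlo uses 5 cohort
seeds at 2 repeats; the full benchmark uses the protocol's 10 repeats.
Oracle equivalences are asserted at 1e-12 (1e-9 for iterative pieces).
The shuffled-label chance band is ±15 accuracy points around 50%, ≈3
binomial standard deviations of a single 60-pattern split, accounting for
the strong correlation between repeats evaluated on the same shuffled
labels.

## Known limitations

* Valley matching assumes the PSD-seeded window is within ~30% of the true
  step interval; heavily smeared spectra (very high jitter) can derail the
  walk. Such trials surface as quarantines, not wrong features.
* The filter-bank delay calibration is empirical (impulse centroid); exact
  per-sample alignment is not guaranteed, only sub-sample-at-12.5 Hz
  accuracy, which is well inside the stride-matching tolerance.
* With 60 patterns and 31 subsets per classifier, subset selection is
  noisy by nature; occurrence counts should be read across seeds, not from
  a single run.
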