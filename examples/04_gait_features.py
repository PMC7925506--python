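"""Extract the five gait features and compare the two classes.

Per trial: mean cycle (stride) duration, cycle regularity (std of stride
durations; near zero for steady gait), cadence in cycles/min, and the two
PSD peak magnitudes.  Pathological gait shows longer, more irregular
strides and weaker angular-rate dynamics.
"""

import numpy as np

import gaitbench as gb

trials = gb.generate_cohort(seed=1)
vectors = [gb.extract_features(t) for t in trials]

for label in ("healthy", "pathological"):
    vs = [v for v in vectors if v.label == label]
    X = np.vstack([v.as_array() for v in vs])
    mean = X.mean(axis=0)
    print(f"{label} (n={len(vs)}):")
    for name, m in zip(gb.FEATURE_NAMES, mean):
        print(f"  {name:>22s}: {m:8.3f}")

fm = gb.normalize_features(gb.features_to_matrix(vectors))
print("\nafter min-max normalization every column spans [0, 1]:")
print("  col mins:", np.round(fm.X.min(axis=0), 3))
print("  col maxs:", np.round(fm.X.max(axis=0), 3))
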