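"""Filter, window, and extract the ten time-domain features.

Shows the windowing arithmetic (10 s of active signal -> 39 windows of
256 ms) and the 390 x 3 single-feature matrix a subject produces, plus the
hand-checkable feature values of a tiny example window.
"""

import numpy as np

from facemg import (
    SimulationConfig,
    default_profiles,
    generate_dataset,
    build_feature_set,
    feature_value,
    segment_signal,
)

# windowing arithmetic
segs = segment_signal(np.zeros(10_000), fs=1000.0, window_ms=256.0)
print(f"10 000 ms at 1000 Hz, 256 ms windows -> {len(segs)} windows per gesture/channel")

# a full subject
dataset = generate_dataset(default_profiles(), SimulationConfig(seed=7), "S1")
fs = build_feature_set(dataset, "MPV")  # filters 30-450 Hz, windows, extracts
print(f"MPV feature set: {fs.matrix.shape[0]} rows x {fs.matrix.shape[1]} channels")
print(fs.to_dataframe().head(3).to_string(index=False))

# hand-checkable window
x = np.array([1.0, -2.0, 3.0, -4.0])
print("\nwindow [1, -2, 3, -4]:")
for m in ("MAV", "RMS", "VAR", "WL", "IEMG", "SSC", "MV", "SSI", "MPV"):
    print(f"  {m:4s} = {feature_value(x, m):.5f}")
print("(MAV = mean |x|, IEMG = sum |x|, SSI = sum x^2, MPV = max |x|, ...)")
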