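"""Simulate inertial windows and extract the 48 statistical features.

Each 6-channel window (3 accelerometer + 3 gyroscope axes, 100 Hz) is
summarised by 8 statistics per channel: mean, median, RMS, min, max,
standard deviation, range, and mean absolute deviation.
"""

from harselect import ActivityModel, extract_table, simulate_dataset
from harselect.features import FEATURE_NAMES

model = ActivityModel.default()  # 18 activity classes, 300-sample windows
windows = simulate_dataset(model, n_per_class=5, seed=42)
table = extract_table(windows)

print(f"{len(windows)} windows -> feature table {table.values.shape}")
print(f"first features: {FEATURE_NAMES[:4]} ...")
row = table.values[0]
for name, value in zip(FEATURE_NAMES[:8], row[:8]):
    print(f"  {name:>14s} = {value:8.3f}")
# The 8 printed values summarise the accelerometer X channel of the
# first window; the remaining 40 repeat the pattern per channel.
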