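# harselect

Metaheuristic wrapper feature selection and gradient-boosting
hyperparameter tuning for sensor-based human activity recognition
(HAR), with a fully synthetic test bed and Shapley interpretability.

HAR classifies physical activities (standing, walking, jumping, …)
from body-worn inertial sensors.  `harselect` targets the KU-HAR data
layout — 6 channels (accelerometer X/Y/Z in m/s², gyroscope X/Y/Z in
rad/s) sampled at 100 Hz, 18 activity classes — and is aimed at
practitioners who want a compact, interpretable classical model instead
of a deep network: each window is reduced to 48 time-domain statistics,
and a metaheuristic jointly selects a feature subset and tunes the
classifier.

## Method

Each channel is summarised by 8 statistics (mean, median, RMS, min,
max, population SD, range, MAD), giving **x ∈ ℝ⁴⁸** per window.  A
candidate solution is a 52-vector: four XGBoost hyperparameters —
n_estimators ∈ [100, 300], learning_rate ∈ [0.001, 0.2],
max_depth ∈ [3, 7], min_child_weight ∈ [1, 10] — plus 48 mask
dimensions in [0, 1], thresholded at 0.5.  Two population metaheuristics
maximise the wrapper fitness (macro F1 on a stratified inner split):

- **GJO** (Golden Jackal Optimization): male/female leaders steer each
  prey with energy E = c1(1 − t/T)(2r − 1); |E| ≥ 1 explores
  (Y₁ = Y_M − E·|Y_M − R_levy·Prey|), |E| < 1 exploits
  (Y₁ = Y_M − E·|R_levy·Y_M − Prey|), new position = (Y₁ + Y₂)/2.
- **WARSO** (War Strategy Optimization): attack
  P + 2ρ(C − King) + R(W·King − P) or defense
  P + 2ρ(King − P_rand) + R·W·(C − P), acceptance only on non-degrading
  fitness, rank-driven weight decay W ← W(1 − R_i/T)^α, and per-iteration
  relocation of the weakest soldier toward the army median and King.

The search runs independently on each of 10 stratified 70/30 folds; the
10 outcomes are consolidated by **majority vote** on hyperparameters
(modal ties broken by earliest fold) and **union** on features.  The
finalized model is evaluated over 10 fresh stratified splits (accuracy,
macro precision/recall/F in %, one-vs-rest AUC; mean ± sample SD), and
explained with Shapley values: exact subset enumeration for ≤ 12
features, the library's native tree-path explainer above that.

See `docs/methods.md` for assumptions, parameter defaults, and
numerical conventions.

## Worked example

Consolidating the bundled reference fold logs (a full-scale 10-fold run
on the real 20,750-window dataset) reproduces the final configurations:

```sh
$ python examples/03_consensus.py
GJO: 23 features (union of 10 folds)
  n_estimators=280  learning_rate=0.116176736  max_depth=7  min_child_weight=1
  features: [1, 5, 6, 7, 8, 10, 11, 14, 15, 20, 21, 23, 24, 27, 30, 32, 34, 36, 38, 39, 41, 45, 47]
WARSO: 44 features (union of 10 folds)
  n_estimators=230  learning_rate=0.2  max_depth=6  min_child_weight=2
  ...
```

GJO consolidates to a compact 23-of-48-feature model; WARSO keeps 44
features with a faster learning rate and shallower trees.  The feature
indices refer to the canonical order (serial 0 = `mean_acc_x`, …,
47 = `mad_gyro_z`).

The other scripts in `examples/` each demonstrate one capability on
small synthetic inputs: `01_extract_features.py` (window → 48
statistics), `02_optimize_fold.py` (wrapper search recovering planted
informative columns), `04_evaluate.py` (repeated stratified
evaluation), `05_explain.py` (Shapley ranking and a margin
decomposition of one prediction).

A `harselect` console command mirrors the pipeline
(`simulate`, `extract-features`, `optimize`, `finalize`, `evaluate`,
`explain`) for shell use; it is a thin layer over the same functions.

## Using real data

`read_kuhar_wide` parses the public wide CSV layout (1803 columns: six
300-sample channel blocks, class id, channel length, serial); nothing
in the package downloads data.  `extract-features` then produces the
49-column feature table and the rest of the pipeline is identical to
the synthetic path.
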