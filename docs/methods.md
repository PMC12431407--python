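# Methods

## Problem and pipeline

`harselect` implements wrapper-based feature selection and
hyperparameter tuning for sensor-based human activity recognition
(HAR).  The input is a set of labelled 6-channel inertial windows
(accelerometer X/Y/Z in m/s², gyroscope X/Y/Z in rad/s, 100 Hz, up to
300 samples per channel, 18 activity classes in the KU-HAR layout).
The pipeline is:

1. **Feature extraction** — each channel is summarised by eight
   time-domain statistics (mean, median, RMS, min, max, SD, range,
   MAD), giving a 48-dimensional vector per window.
2. **Per-fold wrapper optimization** — a metaheuristic searches a
   52-dimensional box: four XGBoost hyperparameters (n_estimators ∈
   [100, 300], learning_rate ∈ [0.001, 0.2], max_depth ∈ [3, 7],
   min_child_weight ∈ [1, 10]) and 48 continuous mask dimensions in
   [0, 1].  Fitness is the macro F1 of a model trained on the selected
   columns.
3. **Consensus** — 10 independent fold optimizations are consolidated
   by majority vote on hyperparameters and union on features.
4. **Evaluation** — the finalized model is trained and scored over 10
   independent stratified 70/30 splits; metrics are means ± sample SD.
5. **Interpretation** — Shapley attributions in raw margin space.

## Statistical features

SD and MAD use the population (1/n) normalisation; the median of an
even-length channel is the mean of the two central order statistics.
These conventions make the algebraic identity RMS² = mean² + SD² exact,
which the suite uses as an extractor invariant.  Feature order is
canonical — 8 statistics per channel, channels in accelerometer-then-
gyroscope, X/Y/Z order — and all integer feature indices in fold logs,
consensus sets and rankings refer to that order.  Only the first
`channel_length` samples of a stored window are used; trailing cells in
the wide CSV layout are opaque padding.

## Optimizers

Both optimizers are continuous maximizers over a box, with population
30 and 50 iterations as the reference budget, greedy/conditional
acceptance, and a running-best trajectory that is monotone by
construction.  Positions leaving the box are clamped; non-finite
coordinates (which the update arithmetic cannot produce unless the
objective misbehaves) are resampled uniformly and logged.

**Golden Jackal Optimization (GJO).**  The best (male) and second-best
(female) population members steer every other member (prey).  The
prey-energy envelope is E = c1·(1 − t/T)·(2r − 1) with r ~ U(0, 1) and
c1 = 1.5 by default, so energy decays linearly in expectation over the
run.  |E| ≥ 1 selects the exploration update
Y1 = YM − E·|YM − R_levy·Prey| (and likewise for the female); |E| < 1
selects the exploitation update Y1 = YM − E·|R_levy·YM − Prey|.  The
new position is (Y1 + Y2)/2, accepted greedily on improvement.
R_levy is a Mantegna Lévy step (β = 1.5, scale 0.01).  The energy
constant, Lévy parameters, and the absolute-value bars around the
distance terms are exposed in configuration; the defaults follow the
original formulation of the algorithm.

**War Strategy Optimization (WARSO).**  Soldiers move in attack
formation, P + 2ρ(C − King) + R(W·King − P), or defense formation,
P + 2ρ(King − P_rand) + R·W·(C − P), with ρ, R ~ U(0, 1), King the
best and C (commander) the second-best member.  The strategy is chosen
per soldier per iteration by a Bernoulli(0.5) draw — the formulation
defines both moves but no selection rule, so an unbiased coin is the
neutral choice, exposed as `attack_probability`.  A move is accepted
only if fitness does not degrade; acceptance increments the soldier's
rank R_i and decays its weight W_i ← W_i·(1 − R_i/T)^α (α = 0.5 by
default, exposed).  After each sweep the single worst soldier is
relocated toward −(1 − R_g)·(P_w − median(P)) + King with
R_g ~ N(0, 1) ("retraining"); uniform random replacement is available
behind the `weak_relocation` switch.  Ranks and weights are frozen on
rejection.

## Wrapper fitness

The fitness of a candidate is the macro F1 of an XGBoost classifier
trained on the candidate's decoded configuration and scored on a
stratified 80/20 inner split of the fold's training partition, fixed
per fold.  Scoring on the training data itself would saturate at 1.0
(the model interpolates), and scoring on the fold's held-out 30% would
leak test information into selection, so the inner split is the only
defensible choice.  The classifier seed is pinned (0) across all
fitness calls so fitness differences reflect the candidate.  A
classifier failure yields fitness 0 with a logged warning rather than
aborting the search.

Decoding rounds integer dimensions to the nearest value and clamps;
mask dimension d selects feature d iff its value ≥ 0.5.  An empty mask
is repaired by selecting the single largest mask dimension (ties to the
lowest index), keeping the objective total.  The threshold bridge was
chosen over stochastic transfer-function binarisation to keep decoding
deterministic and reproducible; as a consequence published fold-wise
feature sets obtained with other binarisation schemes are treated as
worked examples for the consensus stage rather than bit-reproducible
targets.

## Consensus

For each hyperparameter the modal value across the 10 folds wins; among
equally frequent values the one first seen in fold order wins, which
subsumes the all-unique case (fall back to fold 1).  Learning-rate
votes are compared by exact float value: repeats only arise from bound
clamping (e.g. 0.2), so exact comparison is well defined.  The feature
set is the sorted union over folds — every feature selected at least
once is retained.  Fold order is therefore part of the contract and
outcomes must be supplied ordered.

## Evaluation protocol

Folds are independent stratified random 70/30 splits (not a partition);
split i is seeded by (base_seed, i).  Stratification is used because
HAR class frequencies are strongly imbalanced and every class must
appear in each test set.  Per-class precision, recall and F come from
one-vs-rest confusion counts with 0 where a denominator vanishes; macro
values are unweighted class means, and macro F is the mean of per-class
F scores, not the harmonic mean of macro precision and recall.  AUC is
macro one-vs-rest computed from the Mann–Whitney rank statistic with
midrank tie handling.  Across-fold dispersion uses the sample SD
(ddof = 1).  Percentages are reported at 2 decimals and AUC at 5.
Wall-clock train/test times are recorded per fold but never asserted —
they are hardware facts, not model properties.

## Shapley attributions

`exact_shapley` enumerates all 2^d coalitions (refusing d > 12) and
applies the weights |S|!(d − |S| − 1)!/d!, marginalising absent
features by averaging the value function over a background sample
(interventional convention).  It is double precision and satisfies
efficiency, dummy and symmetry to float tolerance; it is the oracle.

`explain_model` delegates large models to the gradient-boosting
library's native tree-path explainer, which returns per-class
contributions plus a bias term in raw margin space.  Margin space is
used because efficiency is exact there; class probabilities pass
through softmax, where additivity does not survive.  Two numerical
facts shape the tests:

- The native explainer emits **single-precision** contributions, so the
  reconstruction residual |E[f] + Σφ − f(x)| against the float32 margin
  is of order 1e−5 on a 230-tree 18-class model.  Efficiency is
  asserted at 1e−6 on the double-precision exact route and at a 1e−4
  single-precision bound on delegated attributions.
- The explainer's path-dependent expectations weight leaves by cover,
  which in XGBoost is a **sum of hessians**.  For softmax objectives
  the hessians vary per row, so path-dependent values cannot coincide
  with uniform-background interventional values even for depth-1 trees.
  With a squared-error objective (unit hessians) and depth-1 trees the
  two semantics coincide exactly, so the cross-route agreement test
  uses a stump-ensemble regression model, where agreement is ~1e−7.

Feature rankings are mean |φ| per feature over a reference sample,
summed across classes, descending with ties toward the lower index.

## Synthetic data

The signal generator emulates the KU-HAR structure: 18 classes, 6
channels, 300-sample windows at 100 Hz.  Channel j of class c is
m_cj + a_cj·sin(2π f_cj t/100 + φ) + N(0, σ²_cj) with a fresh uniform
phase per window.  Defaults: classes 0–6 are static/transitional
(a = 0); classes 7–17 are dynamic with distinct dominant frequencies
(0.8–4.5 Hz, in the gait band); noise SD is 0.3 signal units; baselines
carry a binary-coded orientation offset (channel j holds bit j of the
class id, 4 units per bit) plus N(0, 0.3²) jitter, so class means
separate along axis-aligned cuts — a shallow decision tree can verify
separability, and the 48 extracted features carry redundant class
signal the way orientation-dependent real channels do.

The feature-space generator emits n × 48 tables in which k informative
columns carry class-graded means (adjacent classes separated by
`class_separation` within-class SDs, signs alternating across columns)
and the rest are N(0, 1) noise; the informative indices are recorded in
the table metadata.  It decouples optimizer tests from the extractor.

What the generators do **not** model: real sensor spectra, inter-subject
variability, class imbalance, label noise, or temporal correlation
between windows.  Passing tests therefore demonstrate the correctness
of the machinery (extraction, search, aggregation, evaluation,
attribution), not the difficulty of real HAR data; accuracies on
synthetic data are near-ceiling by construction.

## Problem sizes and budgets

Test and acceptance runs use deliberately scaled-down problems chosen
as the smallest sizes at which each property is identifiable: sphere
benchmarks at population 30 / 50 iterations over 10 seeds;
informative-feature recovery on 600-sample, 48-column benchmarks at
population 15 / 20 iterations over 10 seeds (a reduced budget relative
to the reference 30/50, documented as such); synthetic end-to-end
evaluation at 450 windows over 10 folds.  Full-scale runs on the real
20,750-window dataset use the same code paths with the reference
budget.

## Known limitations

- Only time-domain statistics are extracted; frequency-domain,
  autocorrelation and wavelet features are out of scope.
- The continuous-mask threshold makes selected sets deterministic but
  not comparable bit-for-bit with stochastic binarisation schemes.
- Delegated attributions inherit single-precision output and
  cover-weighted (path-dependent) semantics from the underlying
  library; the exact oracle is limited to 12 features.
- The evaluation protocol draws independent splits rather than a
  partition, so test sets overlap across folds; fold metrics are not
  independent samples.
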