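"""Shapley interpretability: feature ranking and a single-prediction
margin decomposition.

Attributions are computed in raw margin space per class, where
efficiency E[f(x)] + sum(phi) = f(x) holds; features are ranked by mean
|phi| over a test sample, summed across classes.
"""

import numpy as np

from harselect import (
    ActivityModel,
    XGBoostAdapter,
    extract_table,
    finalize,
    load_reference_fold_outcomes,
    make_folds,
    simulate_dataset,
)
from harselect.features import FEATURE_NAMES
from harselect.shapley import explain_model, misclassification_report, rank_features

config = finalize(load_reference_fold_outcomes("gjo"))
table = extract_table(simulate_dataset(ActivityModel.default(), 15, seed=1))
split = make_folds(table.labels, n_folds=1, base_seed=1)[0]
cols = list(config.selected_features)

adapter = XGBoostAdapter.from_config(config)
adapter.fit(table.values[split.train_indices][:, cols],
            table.labels[split.train_indices])

test = table.values[split.test_indices]
atts = explain_model(adapter, config, None, test[:60], FEATURE_NAMES)
ranking = rank_features(atts)
print("top features by mean |phi|:")
for name, value in ranking.top(5):
    print(f"  {name:>14s}  {value:.3f}")

report = misclassification_report(
    adapter, config, test[0],
    true_label=int(table.labels[split.test_indices][0]),
    feature_names=FEATURE_NAMES)
print(f"\ninstance 0: true {report['true_label']}, "
      f"predicted {report['predicted_label']} "
      f"({'correct' if report['correct'] else 'wrong'})")
for c in report["top_contributors_predicted"]:
    print(f"  {c['feature']:>14s}  phi={c['phi']:+.3f}  value={c['value']:.3f}")
# Positive phi values push the margin toward the predicted class; the
# ranking shows which channel statistics carry the class signal.
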