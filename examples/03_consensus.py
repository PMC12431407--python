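"""Consolidate 10 fold-wise optimizer outcomes into one configuration.

Uses the bundled reference fold logs from a full-scale KU-HAR run.
Hyperparameters are aggregated by majority vote (modal ties broken by
earliest fold, all-unique falls back to fold 1) and the feature set by
union over folds.
"""

from harselect import finalize, load_reference_fold_outcomes

for method in ("gjo", "warso"):
    outcomes = load_reference_fold_outcomes(method)
    config = finalize(outcomes)
    print(f"{method.upper()}: {config.n_features} features "
          f"(union of {len(outcomes)} folds)")
    print(f"  n_estimators={config.n_estimators}  "
          f"learning_rate={config.learning_rate}  "
          f"max_depth={config.max_depth}  "
          f"min_child_weight={config.min_child_weight}")
    print(f"  features: {list(config.selected_features)}")
# GJO consolidates to a compact 23-feature model; WARSO keeps 44 of the
# 48 features with a faster learning rate and shallower trees.
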