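{
  "description": "Per-fold test metrics from the same reference KU-HAR experiment as reference_runs.json: 10 stratified 70/30 folds (test size 6225 of 20750). Percent metrics are printed at 2 decimals, AUC at 5.",
  "test_size": 6225,
  "gjo": {
    "accuracy": [93.54, 93.41, 93.93, 93.35, 93.67, 93.77, 93.67, 93.35, 93.43, 93.38],
    "f_score": [92.28, 92.02, 92.82, 91.93, 92.39, 92.34, 91.85, 92.16, 92.16, 92.46],
    "precision": [93.18, 92.72, 93.42, 92.37, 92.92, 92.52, 92.28, 93.06, 93.20, 93.13],
    "recall": [91.58, 91.44, 92.32, 91.60, 91.98, 92.19, 91.48, 91.46, 91.40, 91.91],
    "auc": [0.99675, 0.99715, 0.99754, 0.99729, 0.99663, 0.99736, 0.99816, 0.99724, 0.99703, 0.99579],
    "fold1_correct": 5823
  },
  "warso": {
    "accuracy": [94.17, 94.47, 94.23, 93.72, 93.98, 93.65, 93.83, 93.88, 94.23, 94.07],
    "f_score": [93.03, 93.54, 93.06, 92.47, 92.75, 92.28, 92.15, 92.97, 93.24, 93.28],
    "precision": [93.84, 94.04, 93.57, 92.72, 93.25, 92.79, 92.69, 93.46, 94.22, 94.11],
    "recall": [92.39, 93.12, 92.62, 92.32, 92.35, 91.85, 91.71, 92.55, 92.52, 92.61],
    "auc": [0.99712, 0.99717, 0.99736, 0.99710, 0.99718, 0.99754, 0.99805, 0.99651, 0.99639, 0.99547],
    "fold1_correct": 5860
  }
}
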