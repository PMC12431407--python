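{
  "description": "Worked-example fold logs from a reference KU-HAR wrapper-selection experiment (10 stratified 70/30 folds, population 30, 50 iterations). Feature indices follow the canonical 48-feature serial order.",
  "gjo": [
    {"fold_index": 1, "selected_features": [5, 6, 7, 11, 14, 23, 27, 32, 34, 38, 41], "n_estimators": 279, "learning_rate": 0.116176736, "max_depth": 7, "min_child_weight": 1},
    {"fold_index": 2, "selected_features": [5, 10, 15, 20, 32, 34, 39, 41], "n_estimators": 299, "learning_rate": 0.110572987, "max_depth": 7, "min_child_weight": 1},
    {"fold_index": 3, "selected_features": [6, 8, 10, 20, 21, 27, 30, 32, 36], "n_estimators": 272, "learning_rate": 0.084533705, "max_depth": 7, "min_child_weight": 1},
    {"fold_index": 4, "selected_features": [6, 7, 10, 14, 20, 30, 32, 34, 45, 47], "n_estimators": 186, "learning_rate": 0.126345040, "max_depth": 7, "min_child_weight": 1},
    {"fold_index": 5, "selected_features": [5, 7, 10, 14, 15, 34, 45], "n_estimators": 253, "learning_rate": 0.193675087, "max_depth": 7, "min_child_weight": 1},
    {"fold_index": 6, "selected_features": [5, 7, 8, 10, 23, 24, 34, 41], "n_estimators": 274, "learning_rate": 0.123926983, "max_depth": 7, "min_child_weight": 1},
    {"fold_index": 7, "selected_features": [1, 8, 14, 20, 21, 23, 34], "n_estimators": 280, "learning_rate": 0.179786016, "max_depth": 7, "min_child_weight": 1},
    {"fold_index": 8, "selected_features": [5, 10, 14, 24, 34, 45], "n_estimators": 266, "learning_rate": 0.132827173, "max_depth": 7, "min_child_weight": 1},
    {"fold_index": 9, "selected_features": [5, 6, 14, 20, 23, 32, 34, 36, 41, 45], "n_estimators": 280, "learning_rate": 0.099581423, "max_depth": 7, "min_child_weight": 1},
    {"fold_index": 10, "selected_features": [5, 14, 20, 27, 32, 34, 38, 41], "n_estimators": 278, "learning_rate": 0.143630097, "max_depth": 7, "min_child_weight": 1}
  ],
  "warso": [
    {"fold_index": 1, "selected_features": [1, 5, 16, 17, 18, 21, 22, 23, 24, 25, 29, 30, 35, 36, 40, 41, 44, 46], "n_estimators": 225, "learning_rate": 0.171671644, "max_depth": 6, "min_child_weight": 8},
    {"fold_index": 2, "selected_features": [1, 5, 15, 16, 17, 21, 23, 25, 26, 29, 30, 32, 35, 36, 37, 40, 41, 44, 46], "n_estimators": 219, "learning_rate": 0.177963083, "max_depth": 5, "min_child_weight": 2},
    {"fold_index": 3, "selected_features": [13, 16, 21, 23, 24, 25, 29, 30, 32, 35, 37, 41, 43, 46], "n_estimators": 233, "learning_rate": 0.200000000, "max_depth": 6, "min_child_weight": 8},
    {"fold_index": 4, "selected_features": [1, 5, 6, 15, 16, 17, 18, 23, 24, 25, 26, 27, 28, 29, 30, 35, 36, 40, 41, 43, 44, 46], "n_estimators": 214, "learning_rate": 0.200000000, "max_depth": 6, "min_child_weight": 7},
    {"fold_index": 5, "selected_features": [5, 15, 16, 17, 18, 21, 23, 24, 25, 26, 29, 30, 35, 36, 40, 41, 43, 44, 46], "n_estimators": 254, "learning_rate": 0.177088074, "max_depth": 6, "min_child_weight": 9},
    {"fold_index": 6, "selected_features": [1, 5, 15, 16, 17, 18, 21, 23, 24, 25, 29, 30, 35, 36, 40, 41, 43, 44, 46], "n_estimators": 230, "learning_rate": 0.200000000, "max_depth": 6, "min_child_weight": 8},
    {"fold_index": 7, "selected_features": [1, 4, 5, 6, 7, 8, 9, 10, 11, 15, 16, 17, 26, 30, 31, 33, 38, 39, 40, 42, 43, 44, 47], "n_estimators": 208, "learning_rate": 0.200000000, "max_depth": 4, "min_child_weight": 2},
    {"fold_index": 8, "selected_features": [2, 5, 9, 10, 11, 13, 14, 16, 31, 32, 33, 34, 36, 38, 40, 44, 46, 47], "n_estimators": 211, "learning_rate": 0.172988329, "max_depth": 6, "min_child_weight": 2},
    {"fold_index": 9, "selected_features": [2, 5, 8, 11, 15, 18, 21, 22, 23, 24, 25, 26, 29, 30, 31, 38, 40, 41, 43], "n_estimators": 230, "learning_rate": 0.130140028, "max_depth": 5, "min_child_weight": 2},
    {"fold_index": 10, "selected_features": [1, 9, 11, 12, 13, 15, 16, 21, 24, 25, 26, 32, 35, 36, 37, 38, 40, 41, 43, 44, 45], "n_estimators": 211, "learning_rate": 0.200000000, "max_depth": 6, "min_child_weight": 7}
  ]
}
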