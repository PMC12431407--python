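"""Wrapper fitness and per-fold optimization.

The fitness of a candidate position is the macro F1 score of a
gradient-boosted-tree classifier trained on the candidate's selected
feature columns with its decoded hyperparameters.  F1 is measured on a
stratified 80/20 inner split of the fold's training partition, fixed
per fold: evaluating on training data would saturate at 1.0 (the model
interpolates), and touching the fold's held-out test partition would
leak.  The classifier seed is fixed across fitness calls so fitness
differences reflect the candidate, not classifier randomness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score
from sklearn.model_selection import train_test_split
from xgboost import XGBClassifier

from .features import FeatureTable
from .optimizers import OptimizationResult, optimize
from .space import DecodedConfig, SearchSpace, decode

logger = logging.getLogger(__name__)

ADAPTER_SEED = 0


class XGBoostAdapter:
    """Thin adapter around the gradient-boosted-tree classifier.

    Internally remaps arbitrary label values onto 0..k-1 and back, and
    pins the classifier seed and thread count so fits are deterministic.
    """

    def __init__(self, n_estimators: int, learning_rate: float,
                 max_depth: int, min_child_weight: int,
                 seed: int = ADAPTER_SEED) -> None:
        self.params = dict(
            n_estimators=n_estimators,
            learning_rate=learning_rate,
            max_depth=max_depth,
            min_child_weight=min_child_weight,
        )
        self.seed = seed
        self._model: XGBClassifier | None = None
        self._classes: np.ndarray | None = None

    @classmethod
    def from_config(cls, config: DecodedConfig,
                    seed: int = ADAPTER_SEED) -> "XGBoostAdapter":
        return cls(config.n_estimators, config.learning_rate,
                   config.max_depth, config.min_child_weight, seed=seed)

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "XGBoostAdapter":
        self._classes, encoded = np.unique(labels, return_inverse=True)
        self._model = XGBClassifier(
            **self.params,
            random_state=self.seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
        )
        self._model.fit(features, encoded)
        return self

    @property
    def model(self) -> XGBClassifier:
        if self._model is None:
            raise RuntimeError("adapter is not fitted")
        return self._model

    @property
    def classes_(self) -> np.ndarray:
        if self._classes is None:
            raise RuntimeError("adapter is not fitted")
        return self._classes

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.classes_[self.model.predict(features)]

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        """Per-class probabilities; rows sum to 1, columns follow classes_."""
        return self.model.predict_proba(features)


@dataclass
class FitnessContext:
    """Frozen inner split of one fold's training partition."""

    train_values: np.ndarray
    train_labels: np.ndarray
    eval_values: np.ndarray
    eval_labels: np.ndarray
    adapter_seed: int = ADAPTER_SEED

    @classmethod
    def from_table(cls, table: FeatureTable, inner_fraction: float = 0.2,
                   inner_seed: int = 0) -> "FitnessContext":
        if len(np.unique(table.labels)) < 2:
            raise ValueError("fold training data must contain >= 2 classes")
        idx_train, idx_eval = train_test_split(
            np.arange(table.n_samples),
            test_size=inner_fraction,
            random_state=inner_seed,
            stratify=table.labels,
        )
        return cls(
            train_values=table.values[idx_train],
            train_labels=table.labels[idx_train],
            eval_values=table.values[idx_eval],
            eval_labels=table.labels[idx_eval],
        )


@dataclass
class FoldOutcome:
    """Best configuration found for one fold."""

    fold_index: int
    selected_features: list[int]
    n_estimators: int
    learning_rate: float
    max_depth: int
    min_child_weight: int
    best_fitness: float
    trajectory: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fold_index": self.fold_index,
            "selected_features": list(self.selected_features),
            "n_estimators": self.n_estimators,
            "learning_rate": self.learning_rate,
            "max_depth": self.max_depth,
            "min_child_weight": self.min_child_weight,
            "best_fitness": self.best_fitness,
            "trajectory": list(self.trajectory),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FoldOutcome":
        return cls(
            fold_index=d["fold_index"],
            selected_features=list(d["selected_features"]),
            n_estimators=d["n_estimators"],
            learning_rate=d["learning_rate"],
            max_depth=d["max_depth"],
            min_child_weight=d["min_child_weight"],
            best_fitness=d.get("best_fitness", float("nan")),
            trajectory=list(d.get("trajectory", [])),
        )


def candidate_fitness(position: np.ndarray, context: FitnessContext,
                      space: SearchSpace) -> float:
    """Macro F1 of the decoded candidate on the inner evaluation split."""
    config = decode(position, space)
    cols = config.selected_indices
    try:
        adapter = XGBoostAdapter.from_config(config, seed=context.adapter_seed)
        adapter.fit(context.train_values[:, cols], context.train_labels)
        pred = adapter.predict(context.eval_values[:, cols])
    except Exception:  # noqa: BLE001 - search must survive a bad config
        logger.warning("classifier failed for a candidate; fitness set to 0",
                       exc_info=True)
        return 0.0
    return float(f1_score(context.eval_labels, pred, average="macro",
                          zero_division=0))


def derive_seed(base_seed: int, *tags: int) -> int:
    """Stable child seed below 2**31 from a base seed and integer tags."""
    ss = np.random.SeedSequence([int(base_seed), *[int(t) for t in tags]])
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


def run_fold_optimization(
    fold_train: FeatureTable,
    method: str,
    fold_index: int,
    space: SearchSpace | None = None,
    population: int = 30,
    epochs: int = 50,
    base_seed: int = 42,
    inner_fraction: float = 0.2,
    **optimizer_params,
) -> FoldOutcome:
    """Optimize features + hyperparameters on one fold's training data.

    Reproducible given (base_seed, fold_index): the inner split and the
    optimizer stream are both derived from that pair.
    """
    if space is None:
        space = SearchSpace()
    inner_seed = derive_seed(base_seed, fold_index, 1)
    context = FitnessContext.from_table(fold_train, inner_fraction=inner_fraction,
                                        inner_seed=inner_seed)
    result: OptimizationResult = optimize(
        method,
        lambda pos: candidate_fitness(pos, context, space),
        space,
        population=population,
        epochs=epochs,
        seed=derive_seed(base_seed, fold_index, 2),
        **optimizer_params,
    )
    config = decode(result.best_position, space)
    return FoldOutcome(
        fold_index=fold_index,
        selected_features=config.selected_indices,
        n_estimators=config.n_estimators,
        learning_rate=config.learning_rate,
        max_depth=config.max_depth,
        min_child_weight=config.min_child_weight,
        best_fitness=result.best_fitness,
        trajectory=result.trajectory,
    )
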