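"""Fold-consensus aggregation: majority vote + feature union.

Ten independent fold optimizations produce ten configurations; these
are consolidated into one.  Each hyperparameter takes the value that
occurred most often across folds; among equally frequent values the one
first seen (in fold order) wins, which also covers the all-unique case
where the fold-1 value is kept.  The final feature set is the union of
all fold-wise selections: any feature chosen in at least one fold is
retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .objective import FoldOutcome


@dataclass(frozen=True)
class FinalConfig:
    """Consensus feature set and hyperparameters."""

    selected_features: tuple[int, ...]
    n_estimators: int
    learning_rate: float
    max_depth: int
    min_child_weight: int

    @property
    def n_features(self) -> int:
        return len(self.selected_features)

    def to_dict(self) -> dict:
        return {
            "selected_features": list(self.selected_features),
            "n_features": self.n_features,
            "n_estimators": self.n_estimators,
            "learning_rate": self.learning_rate,
            "max_depth": self.max_depth,
            "min_child_weight": self.min_child_weight,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FinalConfig":
        return cls(
            selected_features=tuple(d["selected_features"]),
            n_estimators=d["n_estimators"],
            learning_rate=d["learning_rate"],
            max_depth=d["max_depth"],
            min_child_weight=d["min_child_weight"],
        )


def majority_vote(values: Sequence):
    """Mode of the fold-ordered values.

    Ties among modes are broken by earliest first occurrence in fold
    order; when every value is unique this reduces to the fold-1 value.
    """
    if len(values) == 0:
        raise ValueError("need at least one value")
    counts: dict = {}
    first_seen: dict = {}
    for i, v in enumerate(values):
        counts[v] = counts.get(v, 0) + 1
        first_seen.setdefault(v, i)
    best_count = max(counts.values())
    modes = [v for v, c in counts.items() if c == best_count]
    return min(modes, key=lambda v: first_seen[v])


def union_features(fold_feature_sets: Iterable[Iterable[int]]) -> list[int]:
    """Sorted union of per-fold feature index sets."""
    union: set[int] = set()
    for s in fold_feature_sets:
        union.update(int(i) for i in s)
    return sorted(union)


def finalize(outcomes: Sequence[FoldOutcome]) -> FinalConfig:
    """Aggregate fold outcomes (in fold order) into one configuration."""
    if len(outcomes) == 0:
        raise ValueError("need at least one fold outcome")
    indices = [o.fold_index for o in outcomes]
    if sorted(indices) != indices:
        raise ValueError("outcomes must be supplied in fold order "
                         "(the tie/fallback rules depend on it)")
    return FinalConfig(
        selected_features=tuple(union_features(o.selected_features for o in outcomes)),
        n_estimators=majority_vote([o.n_estimators for o in outcomes]),
        learning_rate=majority_vote([o.learning_rate for o in outcomes]),
        max_depth=majority_vote([o.max_depth for o in outcomes]),
        min_child_weight=majority_vote([o.min_child_weight for o in outcomes]),
    )
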