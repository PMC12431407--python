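"""Shapley-value interpretability.

Two routes are provided.  ``exact_shapley`` enumerates every feature
subset and applies the Shapley weights |S|!(|F|-|S|-1)!/|F|! directly,
marginalising absent features by averaging the value function over a
background sample (the interventional convention); it is tractable for
at most 12 features and serves as the verifiable oracle.
``explain_model`` delegates to the gradient-boosting library's native
tree-path explainer (per-class contribution output) for the full-size
models, explaining raw margins per class -- efficiency
f(x) = E[f(x)] + sum(phi) is exact in margin space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import factorial
from typing import Callable, Sequence

import numpy as np
import xgboost

from .consensus import FinalConfig
from .objective import XGBoostAdapter

MAX_EXACT_FEATURES = 12


@dataclass
class Attribution:
    """Per-feature contributions to one model output.

    ``base_value`` is the expected model output over the background;
    contributions satisfy base_value + sum(phi) = model_output.
    """

    phi: np.ndarray
    base_value: float
    model_output: float
    feature_values: np.ndarray
    class_label: object = None
    feature_names: tuple[str, ...] | None = None

    @property
    def efficiency_gap(self) -> float:
        return float(abs(self.base_value + self.phi.sum() - self.model_output))


def _shapley_weights(n_features: int) -> np.ndarray:
    """weight[s] = s! (n-s-1)! / n! for coalition size s."""
    n = n_features
    return np.array(
        [factorial(s) * factorial(n - s - 1) / factorial(n) for s in range(n)]
    )


def exact_shapley(
    value_fn: Callable[[np.ndarray], np.ndarray],
    instance: np.ndarray,
    background: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> Attribution:
    """Brute-force Shapley attribution by full subset enumeration.

    ``value_fn`` maps an (m, d) matrix to m real outputs.  The value of
    a coalition S is the mean of ``value_fn`` over the background with
    the columns in S replaced by the instance's values.  Refuses more
    than 12 features (4096 coalitions); larger models go through
    ``explain_model``.
    """
    instance = np.asarray(instance, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    d = instance.size
    if d > MAX_EXACT_FEATURES:
        raise ValueError(
            f"exact enumeration is limited to {MAX_EXACT_FEATURES} features "
            f"(got {d}); use explain_model for larger models"
        )
    if background.shape[1] != d:
        raise ValueError("background width must match the instance")

    # coalition values, indexed by bitmask
    values = np.empty(1 << d)
    for mask in range(1 << d):
        hybrid = background.copy()
        for i in range(d):
            if mask >> i & 1:
                hybrid[:, i] = instance[i]
        values[mask] = float(np.mean(value_fn(hybrid)))

    weights = _shapley_weights(d)
    phi = np.zeros(d)
    others = list(range(d))
    for i in range(d):
        rest = [j for j in others if j != i]
        for size in range(d):
            for subset in combinations(rest, size):
                mask = sum(1 << j for j in subset)
                phi[i] += weights[size] * (values[mask | (1 << i)] - values[mask])
    return Attribution(
        phi=phi,
        base_value=values[0],
        model_output=values[(1 << d) - 1],
        feature_values=instance,
        feature_names=tuple(feature_names) if feature_names is not None else None,
    )


def _as_booster(model) -> tuple[xgboost.Booster, np.ndarray | None]:
    if isinstance(model, XGBoostAdapter):
        return model.model.get_booster(), model.classes_
    if isinstance(model, xgboost.Booster):
        return model, None
    if hasattr(model, "get_booster"):  # sklearn-wrapped XGBoost estimator
        return model.get_booster(), getattr(model, "classes_", None)
    raise TypeError(f"cannot extract a booster from {type(model).__name__}")


def tree_attributions(
    model,
    instances: np.ndarray,
) -> list[list[Attribution]]:
    """Delegated tree-path attributions, one list of per-output
    Attributions per instance, in raw margin space.

    ``model`` may be an :class:`XGBoostAdapter`, a fitted sklearn-style
    XGBoost estimator, or a raw ``Booster``.  Contributions come from
    the library's native tree-path explainer, which emits single
    precision; the residual base + sum(phi) - margin is therefore of
    order 1e-5 on deep multiclass models (see ``efficiency_gap``).
    """
    instances = np.atleast_2d(np.asarray(instances, dtype=float))
    booster, classes = _as_booster(model)
    dmat = xgboost.DMatrix(instances)
    contribs = np.asarray(booster.predict(dmat, pred_contribs=True), dtype=float)
    margins = np.asarray(booster.predict(dmat, output_margin=True), dtype=float)
    if contribs.ndim == 2:  # single-output model: one margin column
        contribs = contribs[:, None, :]
        margins = margins.reshape(len(instances), 1)
    if classes is None:
        classes = np.arange(contribs.shape[1])
    out: list[list[Attribution]] = []
    for i in range(len(instances)):
        per_class = []
        for k in range(contribs.shape[1]):
            phi = contribs[i, k, :-1]
            base = float(contribs[i, k, -1])
            per_class.append(
                Attribution(
                    phi=phi,
                    base_value=base,
                    model_output=float(margins[i, k]) if margins.ndim == 2
                    else float(margins[i]),
                    feature_values=instances[i],
                    class_label=classes[k] if k < len(classes) else k,
                )
            )
        out.append(per_class)
    return out


def explain_model(
    adapter: XGBoostAdapter,
    final_config: FinalConfig,
    table_values: np.ndarray,
    instances: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> list[list[Attribution]]:
    """Per-class attributions for instances, restricted to the final
    configuration's feature columns.

    ``table_values`` and ``instances`` are full-width feature matrices;
    columns are subset here so callers need not track the selection.
    """
    cols = list(final_config.selected_features)
    del table_values  # reference data reserved for future background use
    attributions = tree_attributions(adapter, np.atleast_2d(instances)[:, cols])
    if feature_names is not None:
        selected_names = tuple(feature_names[c] for c in cols)
        for per_class in attributions:
            for att in per_class:
                att.feature_names = selected_names
    return attributions


@dataclass
class FeatureRanking:
    """Features ordered by mean |phi| (summed over classes)."""

    names: list[str]
    mean_abs_phi: np.ndarray
    order: list[int] = field(default_factory=list)

    def top(self, k: int) -> list[tuple[str, float]]:
        return [(self.names[i], float(self.mean_abs_phi[i])) for i in self.order[:k]]


def rank_features(
    attributions: Sequence[Sequence[Attribution]] | Sequence[Attribution],
    feature_names: Sequence[str] | None = None,
) -> FeatureRanking:
    """Mean |phi| per feature over instances, summed over classes.

    Accepts either flat attributions or per-instance lists of per-class
    attributions.  Ordering is descending with ties broken toward the
    lower feature index.
    """
    flat: list[list[Attribution]] = []
    for item in attributions:
        flat.append(list(item) if isinstance(item, (list, tuple)) else [item])
    if not flat:
        raise ValueError("need at least one attribution")
    d = flat[0][0].phi.size
    totals = np.zeros(d)
    for per_class in flat:
        for att in per_class:
            totals += np.abs(att.phi)
    mean_abs = totals / len(flat)
    if feature_names is None:
        feature_names = flat[0][0].feature_names or tuple(
            f"f{i}" for i in range(d)
        )
    order = sorted(range(d), key=lambda i: (-mean_abs[i], i))
    return FeatureRanking(names=list(feature_names), mean_abs_phi=mean_abs,
                          order=order)


def misclassification_report(
    adapter: XGBoostAdapter,
    final_config: FinalConfig,
    instance: np.ndarray,
    true_label: object,
    feature_names: Sequence[str] | None = None,
    top_k: int = 5,
) -> dict:
    """Per-class margin decomposition for a single prediction.

    Mirrors a decision/waterfall reading: the margin f(x) for every
    class, plus the top signed contributors for the true and predicted
    classes, so a wrong prediction can be traced to the features that
    pushed the margin across.
    """
    attributions = explain_model(adapter, final_config, None,
                                 np.atleast_2d(instance), feature_names)[0]
    margins = {att.class_label: att.model_output for att in attributions}
    predicted = max(margins, key=margins.get)

    def _top(att: Attribution) -> list[dict]:
        order = np.argsort(-np.abs(att.phi))[:top_k]
        names = att.feature_names or [f"f{i}" for i in range(att.phi.size)]
        return [
            {"feature": names[i], "phi": float(att.phi[i]),
             "value": float(att.feature_values[i])}
            for i in order
        ]

    by_class = {att.class_label: att for att in attributions}
    return {
        "true_label": true_label,
        "predicted_label": predicted,
        "correct": bool(predicted == true_label),
        "margins": {str(k): float(v) for k, v in margins.items()},
        "top_contributors_true": _top(by_class[true_label])
        if true_label in by_class else [],
        "top_contributors_predicted": _top(by_class[predicted]),
    }
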