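"""Bundled worked-example data from a reference KU-HAR experiment.

Ships the fold-wise optimizer outcomes and per-fold test metrics of a
full-scale wrapper-selection run on the real 20,750-window dataset.
The fold logs are the canonical worked example for the consensus rules
(majority vote + feature union), and the metric tables anchor the
reporting conventions (macro averaging, sample SD, rounding).
"""

from __future__ import annotations

import json
from importlib import resources

from .objective import FoldOutcome

_PACKAGE = "harselect.data"


def _load(name: str) -> dict:
    with resources.files(_PACKAGE).joinpath(name).open() as fh:
        return json.load(fh)


def load_reference_fold_outcomes(method: str) -> list[FoldOutcome]:
    """Fold outcomes of the reference run for 'gjo' or 'warso'."""
    data = _load("reference_runs.json")
    if method not in ("gjo", "warso"):
        raise ValueError("method must be 'gjo' or 'warso'")
    return [
        FoldOutcome(
            fold_index=d["fold_index"],
            selected_features=list(d["selected_features"]),
            n_estimators=d["n_estimators"],
            learning_rate=d["learning_rate"],
            max_depth=d["max_depth"],
            min_child_weight=d["min_child_weight"],
            best_fitness=float("nan"),
        )
        for d in data[method]
    ]


def load_reference_metrics() -> dict:
    """Per-fold test metrics (percent / AUC) of the reference run."""
    return _load("reference_metrics.json")
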