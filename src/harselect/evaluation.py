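"""Validation protocol: repeated stratified 70/30 splits and metrics.

The protocol draws ``n_folds`` independent stratified random splits
(70% train / 30% test by default), trains the finalized model on each
training partition, and reports accuracy, macro precision, macro
recall, macro F-score (all in percent), one-vs-rest AUC, and wall-clock
train/test times per fold, plus the mean and sample (ddof = 1) standard
deviation across folds.  Macro F is the unweighted mean of per-class F
scores (not the harmonic mean of macro precision and macro recall).
A seed sweep repeats the whole protocol under different base seeds.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import train_test_split

from .consensus import FinalConfig
from .features import FeatureTable
from .objective import XGBoostAdapter, derive_seed

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldSplit:
    train_indices: np.ndarray
    test_indices: np.ndarray


@dataclass
class MetricsReport:
    """Per-fold metrics; percentages in [0, 100], AUC in [0, 1]."""

    accuracy: float
    precision: float
    recall: float
    f_score: float
    auc: float | None = None
    per_class: dict = field(default_factory=dict)
    confusion: np.ndarray | None = None
    train_time_s: float | None = None
    test_time_s: float | None = None

    def to_dict(self) -> dict:
        d = {
            "accuracy": round(self.accuracy, 2),
            "precision": round(self.precision, 2),
            "recall": round(self.recall, 2),
            "f_score": round(self.f_score, 2),
        }
        if self.auc is not None:
            d["auc"] = round(self.auc, 5)
        if self.train_time_s is not None:
            d["train_time_s"] = self.train_time_s
            d["test_time_s"] = self.test_time_s
        return d


def make_folds(labels: np.ndarray, n_folds: int = 10,
               test_fraction: float = 0.30,
               base_seed: int = 42) -> list[FoldSplit]:
    """n_folds independent stratified train/test splits.

    Split i is seeded from (base_seed, i), so each fold is individually
    reproducible and folds differ across base seeds.
    """
    labels = np.asarray(labels)
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples for stratification")
    indices = np.arange(len(labels))
    folds = []
    for i in range(n_folds):
        train_idx, test_idx = train_test_split(
            indices,
            test_size=test_fraction,
            random_state=derive_seed(base_seed, i, 7),
            stratify=labels,
        )
        folds.append(FoldSplit(train_indices=np.sort(train_idx),
                               test_indices=np.sort(test_idx)))
    return folds


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     classes: np.ndarray | None = None) -> np.ndarray:
    """c x c counts; rows are actual classes, columns predicted."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


def metrics_from_confusion(cm: np.ndarray) -> MetricsReport:
    """Accuracy and macro precision/recall/F from a confusion matrix.

    Per-class metrics use one-vs-rest TP/FP/FN counts, with 0 where a
    denominator vanishes; macro values are unweighted class means.
    Everything is reported in percent.
    """
    cm = np.asarray(cm)
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f = np.where(precision + recall > 0,
                     2 * precision * recall / (precision + recall), 0.0)
    per_class = {
        "precision": (100 * precision).tolist(),
        "recall": (100 * recall).tolist(),
        "f_score": (100 * f).tolist(),
    }
    return MetricsReport(
        accuracy=float(100.0 * tp.sum() / total),
        precision=float(100.0 * precision.mean()),
        recall=float(100.0 * recall.mean()),
        f_score=float(100.0 * f.mean()),
        per_class=per_class,
        confusion=cm,
    )


def ovr_auc(y_true: np.ndarray, scores: np.ndarray,
            classes: np.ndarray | None = None) -> float:
    """Macro one-vs-rest ROC AUC via the Mann-Whitney rank statistic.

    For each class, its score column ranks positives against the rest
    (midranks for ties); classes absent from ``y_true`` are skipped with
    a warning.  The macro value is the unweighted mean over classes.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if classes is None:
        classes = np.unique(y_true)
    if scores.shape != (len(y_true), len(classes)):
        raise ValueError("scores must be (n_samples, n_classes)")
    aucs = []
    for k, c in enumerate(classes):
        pos = y_true == c
        n_pos = int(pos.sum())
        n_neg = len(y_true) - n_pos
        if n_pos == 0 or n_neg == 0:
            logger.warning("class %r absent from one side; skipped in AUC", c)
            continue
        ranks = rankdata(scores[:, k])  # midranks
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        aucs.append(auc)
    if not aucs:
        raise ValueError("no class admits an AUC")
    return float(np.mean(aucs))


def evaluate_split(adapter: XGBoostAdapter, test_values: np.ndarray,
                   test_labels: np.ndarray) -> MetricsReport:
    """Metrics of a fitted adapter on one test partition."""
    t0 = time.perf_counter()
    pred = adapter.predict(test_values)
    scores = adapter.predict_scores(test_values)
    test_time = time.perf_counter() - t0
    cm = confusion_matrix(test_labels, pred, classes=adapter.classes_)
    report = metrics_from_confusion(cm)
    report.auc = ovr_auc(test_labels, scores, classes=adapter.classes_)
    report.test_time_s = test_time
    return report


@dataclass
class CrossValidationResult:
    fold_reports: list[MetricsReport]
    mean: dict
    sd: dict

    def to_dict(self) -> dict:
        return {
            "folds": [r.to_dict() for r in self.fold_reports],
            "mean": self.mean,
            "sd": self.sd,
        }


def summarize(reports: Sequence[MetricsReport]) -> tuple[dict, dict]:
    """Mean and sample SD (ddof = 1) of the headline metrics."""
    fields = ["accuracy", "f_score", "precision", "recall", "auc"]
    mean: dict = {}
    sd: dict = {}
    for name in fields:
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        if np.any(np.isnan(vals)):
            continue
        digits = 5 if name == "auc" else 2
        mean[name] = round(float(vals.mean()), digits)
        sd[name] = round(float(vals.std(ddof=1)) if len(vals) > 1 else 0.0, 3)
    return mean, sd


def cross_validate(final_config: FinalConfig, table: FeatureTable,
                   n_folds: int = 10, test_fraction: float = 0.30,
                   base_seed: int = 42) -> CrossValidationResult:
    """Train/evaluate the finalized model over independent 70/30 splits."""
    cols = list(final_config.selected_features)
    if max(cols) >= table.n_features:
        raise ValueError("final_config refers to features beyond the table")
    folds = make_folds(table.labels, n_folds=n_folds,
                       test_fraction=test_fraction, base_seed=base_seed)
    reports = []
    for split in folds:
        train = table.subset(split.train_indices)
        test = table.subset(split.test_indices)
        adapter = XGBoostAdapter(
            final_config.n_estimators, final_config.learning_rate,
            final_config.max_depth, final_config.min_child_weight,
        )
        t0 = time.perf_counter()
        adapter.fit(train.values[:, cols], train.labels)
        train_time = time.perf_counter() - t0
        report = evaluate_split(adapter, test.values[:, cols], test.labels)
        report.train_time_s = train_time
        reports.append(report)
    mean, sd = summarize(reports)
    return CrossValidationResult(fold_reports=reports, mean=mean, sd=sd)


def seed_sweep(final_config: FinalConfig, table: FeatureTable,
               seeds: Sequence[int], n_folds: int = 10,
               test_fraction: float = 0.30) -> dict[int, CrossValidationResult]:
    """Repeat the whole protocol under each external seed."""
    if len(seeds) == 0:
        raise ValueError("need at least one seed")
    return {
        int(s): cross_validate(final_config, table, n_folds=n_folds,
                               test_fraction=test_fraction, base_seed=int(s))
        for s in seeds
    }
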