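"""Synthetic inertial data emulating the KU-HAR layout.

Two generators are provided.  The signal generator produces labelled
6-channel windows (18 activity classes by default: 7 static or
transitional classes with zero oscillation, 11 dynamic classes with
distinct dominant frequencies) so the full pipeline -- extraction,
optimization, evaluation, interpretation -- runs without the real
dataset.  The feature-space generator emits benchmark tables with a
known set of informative columns, decoupling optimizer tests from
feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureTable, N_FEATURES, SignalWindow

DEFAULT_N_CLASSES = 18
DEFAULT_WINDOW_LENGTH = 300
SAMPLE_RATE = 100.0
N_CHANNELS = 6

# Classes 0-6 mirror static postures and postural transitions (no
# sustained oscillation); 7-17 mirror dynamic movements with distinct
# dominant frequencies in the gait band.
_STATIC_CLASSES = 7


def _default_model_params(
    n_classes: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per (class, channel) baseline, amplitude, frequency, noise SD."""
    baseline = np.empty((n_classes, N_CHANNELS))
    amplitude = np.zeros((n_classes, N_CHANNELS))
    frequency = np.zeros((n_classes, N_CHANNELS))
    noise_sd = np.full((n_classes, N_CHANNELS), 0.3)
    for c in range(n_classes):
        # distinct device orientation per activity: a binary-coded gravity
        # component across channels (channel j carries bit j of the class
        # id) plus small random offsets, so class means separate cleanly
        # along axis-aligned cuts relative to the noise floor
        baseline[c] = 0.3 * rng.standard_normal(N_CHANNELS)
        for j in range(N_CHANNELS):
            baseline[c, j] += 4.0 * ((c >> j) & 1)
        if c >= _STATIC_CLASSES:
            dyn = c - _STATIC_CLASSES
            amplitude[c] = 1.0 + 0.5 * rng.random(N_CHANNELS)
            frequency[c] = 0.8 + 0.35 * dyn + 0.05 * rng.random(N_CHANNELS)
    return baseline, amplitude, frequency, noise_sd


@dataclass
class ActivityModel:
    """Sinusoid-plus-noise signal model per (class, channel).

    Channel j of class c is m_cj + a_cj * sin(2*pi*f_cj*t/rate + phi)
    + N(0, sigma_cj^2) noise, with a fresh uniform phase per window.
    Static classes have a_cj = 0.
    """

    baseline: np.ndarray
    amplitude: np.ndarray
    frequency: np.ndarray
    noise_sd: np.ndarray
    window_length: int = DEFAULT_WINDOW_LENGTH
    sample_rate: float = SAMPLE_RATE

    def __post_init__(self) -> None:
        shape = np.asarray(self.baseline).shape
        for name in ("amplitude", "frequency", "noise_sd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != baseline shape {shape}")
            setattr(self, name, arr)
        self.baseline = np.asarray(self.baseline, dtype=float)
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be non-negative")
        if np.any(self.frequency < 0) or np.any(self.frequency >= self.sample_rate / 2):
            raise ValueError("frequencies must lie in [0, sample_rate/2)")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")

    @property
    def n_classes(self) -> int:
        return self.baseline.shape[0]

    @classmethod
    def default(cls, n_classes: int = DEFAULT_N_CLASSES, seed: int = 0) -> "ActivityModel":
        rng = np.random.default_rng(seed)
        b, a, f, s = _default_model_params(n_classes, rng)
        return cls(baseline=b, amplitude=a, frequency=f, noise_sd=s)


def simulate_window(
    model: ActivityModel, class_id: int, rng: np.random.Generator
) -> SignalWindow:
    """Draw one labelled window from the model."""
    if not 0 <= class_id < model.n_classes:
        raise ValueError(f"class_id {class_id} outside [0, {model.n_classes})")
    t = np.arange(model.window_length)
    channels = []
    for j in range(N_CHANNELS):
        phi = rng.uniform(0.0, 2.0 * np.pi)
        x = (
            model.baseline[class_id, j]
            + model.amplitude[class_id, j]
            * np.sin(2.0 * np.pi * model.frequency[class_id, j] * t / model.sample_rate + phi)
            + rng.normal(0.0, model.noise_sd[class_id, j], size=model.window_length)
        )
        channels.append(x)
    return SignalWindow(channels=tuple(channels), label=class_id,
                        sample_rate=model.sample_rate)


def simulate_dataset(
    model: ActivityModel, n_per_class: int, seed: int
) -> list[SignalWindow]:
    """Class-balanced window set, deterministic given the seed."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    windows = []
    for c in range(model.n_classes):
        for _ in range(n_per_class):
            windows.append(simulate_window(model, c, rng))
    return windows


@dataclass
class BenchmarkSpec:
    """Feature-space benchmark: k informative columns among noise.

    Informative columns carry class-dependent means separated by
    ``class_separation`` within-class standard deviations between
    adjacent classes; the rest are class-independent N(0,1) noise.
    """

    n_samples: int = 600
    n_features: int = N_FEATURES
    k_informative: int = 8
    class_separation: float = 2.0
    n_classes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.k_informative <= self.n_features:
            raise ValueError("k_informative must be in [1, n_features]")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


def make_benchmark_features(spec: BenchmarkSpec) -> FeatureTable:
    """Generate the benchmark table; informative column indices are
    recorded in the table's ``metadata['informative_indices']``."""
    rng = np.random.default_rng(spec.seed)
    labels = np.arange(spec.n_samples) % spec.n_classes
    rng.shuffle(labels)
    values = rng.standard_normal((spec.n_samples, spec.n_features))
    informative = np.sort(
        rng.choice(spec.n_features, size=spec.k_informative, replace=False)
    )
    # alternate the sign of the class gradient across informative columns
    # so no single direction dominates
    signs = np.where(np.arange(spec.k_informative) % 2 == 0, 1.0, -1.0)
    for pos, j in enumerate(informative):
        values[:, j] += signs[pos] * spec.class_separation * labels
    names = tuple(f"f{i:02d}" for i in range(spec.n_features))
    if spec.n_features == N_FEATURES:
        from .features import FEATURE_NAMES

        names = FEATURE_NAMES
    return FeatureTable(
        values=values,
        labels=labels,
        feature_names=names,
        metadata={"informative_indices": [int(j) for j in informative]},
    )
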