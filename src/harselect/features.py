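"""Statistical feature extraction from 6-channel inertial windows.

Each window carries three accelerometer axes (m/s^2) and three gyroscope
axes (rad/s) sampled at 100 Hz.  Every channel is summarised by eight
time-domain statistics -- mean, median, RMS, minimum, maximum, standard
deviation, range and mean absolute deviation -- yielding a 48-dimensional
feature vector per window.  Standard deviation and MAD use the population
(1/n) normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CHANNEL_NAMES = ("acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z")
STAT_NAMES = ("mean", "median", "rms", "min", "max", "std", "range", "mad")

#: Canonical feature order: 8 statistics per channel, channels in
#: accelerometer-then-gyroscope, X/Y/Z order.  Integer feature indices
#: used throughout the package (fold logs, consensus sets, rankings)
#: refer to positions in this tuple.
FEATURE_NAMES = tuple(
    f"{stat}_{chan}" for chan in CHANNEL_NAMES for stat in STAT_NAMES
)

N_FEATURES = len(FEATURE_NAMES)  # 48
LABEL_COLUMN = "activity"


@dataclass(frozen=True)
class ChannelSummary:
    """Eight time-domain statistics of a single sensor channel."""

    mean: float
    median: float
    rms: float
    min: float
    max: float
    std: float
    range: float
    mad: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mean, self.median, self.rms, self.min, self.max,
             self.std, self.range, self.mad]
        )


@dataclass(frozen=True)
class SignalWindow:
    """One labelled subsample: six channels of finite samples at 100 Hz.

    Channels need not share a length (windows are truncated to the
    recorded channel length), but each must be non-empty.
    """

    channels: tuple[np.ndarray, ...]
    label: int
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        if len(self.channels) != len(CHANNEL_NAMES):
            raise ValueError(
                f"expected {len(CHANNEL_NAMES)} channels, got {len(self.channels)}"
            )
        chans = tuple(np.asarray(c, dtype=float) for c in self.channels)
        for name, c in zip(CHANNEL_NAMES, chans):
            if c.ndim != 1 or c.size == 0:
                raise ValueError(f"channel {name} must be a non-empty 1-D sequence")
            if not np.all(np.isfinite(c)):
                raise ValueError(f"channel {name} contains non-finite samples")
        object.__setattr__(self, "channels", chans)


@dataclass
class FeatureTable:
    """An n x 48 feature matrix with labels, in canonical column order."""

    values: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("values and labels disagree on sample count")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("values and feature_names disagree on width")
        self.feature_names = tuple(self.feature_names)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df[LABEL_COLUMN] = self.labels
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        if LABEL_COLUMN not in df.columns:
            raise ValueError(f"missing {LABEL_COLUMN!r} column")
        names = tuple(c for c in df.columns if c != LABEL_COLUMN)
        return cls(
            values=df[list(names)].to_numpy(dtype=float),
            labels=df[LABEL_COLUMN].to_numpy(),
            feature_names=names,
        )

    def subset(self, rows: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            values=self.values[rows],
            labels=self.labels[rows],
            feature_names=self.feature_names,
            metadata=dict(self.metadata),
        )


def summarize_channel(x: Sequence[float]) -> ChannelSummary:
    """Compute the eight channel statistics.

    SD is the population form sqrt(mean((x - mu)^2)); MAD is
    mean(|x - mu|); the median of an even-length channel is the mean of
    the two central order statistics.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("channel must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(arr)):
        raise ValueError("channel contains non-finite samples")
    mu = float(arr.mean())
    return ChannelSummary(
        mean=mu,
        median=float(np.median(arr)),
        rms=float(np.sqrt(np.mean(arr ** 2))),
        min=float(arr.min()),
        max=float(arr.max()),
        std=float(arr.std(ddof=0)),
        range=float(arr.max() - arr.min()),
        mad=float(np.mean(np.abs(arr - mu))),
    )


def extract_features(window: SignalWindow) -> np.ndarray:
    """48-vector of statistics: 8 per channel, channels in canonical order."""
    return np.concatenate(
        [summarize_channel(c).as_array() for c in window.channels]
    )


def extract_table(windows: Sequence[SignalWindow]) -> FeatureTable:
    """Row-wise feature extraction over a sequence of windows."""
    if len(windows) == 0:
        raise ValueError("need at least one window")
    values = np.vstack([extract_features(w) for w in windows])
    labels = np.array([w.label for w in windows])
    return FeatureTable(values=values, labels=labels)
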