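"""Readers and writers for the KU-HAR wide-CSV dialect and artifacts.

The wide dialect stores one subsample per row: columns 1-300
accelerometer X, 301-600 accelerometer Y, 601-900 accelerometer Z,
901-1200 gyroscope X, 1201-1500 gyroscope Y, 1501-1800 gyroscope Z
(1-based, as the dataset documents them), column 1801 the activity
class (0-17), column 1802 the usable channel length, column 1803 the
subsample serial.  Cells beyond the channel length are opaque padding
and are ignored on read.  A 1801-column variant without the two
metadata columns is accepted (full channel length assumed), which is
the layout synthetic files use.

Feature tables are plain CSV with the 48 canonical feature names plus
an ``activity`` label column; fold outcomes, final configurations and
metric reports are JSON; run configuration is YAML.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .consensus import FinalConfig
from .features import FEATURE_NAMES, LABEL_COLUMN, FeatureTable, SignalWindow
from .objective import FoldOutcome

CHANNEL_SLOT = 300
N_CHANNELS = 6
N_SIGNAL_COLUMNS = CHANNEL_SLOT * N_CHANNELS  # 1800
WIDE_COLUMNS = N_SIGNAL_COLUMNS + 3  # class, channel length, serial
BARE_COLUMNS = N_SIGNAL_COLUMNS + 1  # class only
N_CLASSES = 18


class MalformedRowError(ValueError):
    """A wide-CSV row with the wrong number of fields."""


@dataclass(frozen=True)
class RawWindowRecord:
    """One parsed subsample of the wide dialect."""

    channels: tuple[np.ndarray, ...]
    class_id: int
    channel_length: int
    serial: int

    def to_window(self) -> SignalWindow:
        return SignalWindow(channels=self.channels, label=self.class_id)


def read_kuhar_wide(path: str | Path) -> list[RawWindowRecord]:
    """Parse a wide-CSV file into window records.

    Channels are truncated to the recorded channel length; rows with a
    field count other than 1803 (or the bare 1801 variant) raise
    :class:`MalformedRowError` naming the row, and out-of-range class
    ids raise ``ValueError``.
    """
    records: list[RawWindowRecord] = []
    with open(path, newline="") as fh:
        for row_number, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            if len(row) not in (WIDE_COLUMNS, BARE_COLUMNS):
                raise MalformedRowError(
                    f"row {row_number}: expected {WIDE_COLUMNS} (or "
                    f"{BARE_COLUMNS}) fields, found {len(row)}"
                )
            values = np.array(row[:N_SIGNAL_COLUMNS], dtype=float)
            class_id = int(float(row[N_SIGNAL_COLUMNS]))
            if not 0 <= class_id < N_CLASSES:
                raise ValueError(
                    f"row {row_number}: class id {class_id} outside 0-{N_CLASSES - 1}"
                )
            if len(row) == WIDE_COLUMNS:
                channel_length = int(float(row[N_SIGNAL_COLUMNS + 1]))
                serial = int(float(row[N_SIGNAL_COLUMNS + 2]))
            else:
                channel_length, serial = CHANNEL_SLOT, row_number - 1
            if not 1 <= channel_length <= CHANNEL_SLOT:
                raise ValueError(
                    f"row {row_number}: channel length {channel_length} "
                    f"outside 1-{CHANNEL_SLOT}"
                )
            channels = tuple(
                values[j * CHANNEL_SLOT: j * CHANNEL_SLOT + channel_length]
                for j in range(N_CHANNELS)
            )
            for j, c in enumerate(channels):
                if not np.all(np.isfinite(c)):
                    raise ValueError(
                        f"row {row_number}: non-finite sample in channel {j}"
                    )
            records.append(
                RawWindowRecord(channels=channels, class_id=class_id,
                                channel_length=channel_length, serial=serial)
            )
    return records


def write_kuhar_wide(records: Sequence[RawWindowRecord], path: str | Path) -> None:
    """Serialise records in the wide dialect (zero padding past the
    channel length)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for rec in records:
            row: list[str] = []
            for c in rec.channels:
                padded = np.zeros(CHANNEL_SLOT)
                padded[: len(c)] = c
                row.extend(repr(float(v)) for v in padded)
            row.extend([str(rec.class_id), str(rec.channel_length), str(rec.serial)])
            writer.writerow(row)


def windows_to_records(windows: Sequence[SignalWindow]) -> list[RawWindowRecord]:
    """Wrap simulated windows as wide-dialect records."""
    records = []
    for serial, w in enumerate(windows):
        records.append(
            RawWindowRecord(
                channels=w.channels,
                class_id=int(w.label),
                channel_length=len(w.channels[0]),
                serial=serial,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Feature tables


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """CSV with the canonical 48 feature columns plus ``activity``.

    Values are printed at full precision so a write/read round trip is
    bit-identical.
    """
    if tuple(table.feature_names) != FEATURE_NAMES:
        raise ValueError("feature table columns must match the canonical names")
    df = table.to_dataframe()
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = list(FEATURE_NAMES) + [LABEL_COLUMN]
    if list(df.columns) != expected:
        raise ValueError("feature table header does not match the canonical schema")
    if not np.all(np.isfinite(df[list(FEATURE_NAMES)].to_numpy())):
        raise ValueError("feature table contains non-finite values")
    return FeatureTable.from_dataframe(df)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Protocol-level settings for a full optimization + evaluation run."""

    base_seed: int = 42
    external_seeds: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 35, 40, 45, 50)
    n_folds: int = 10
    test_fraction: float = 0.30
    population: int = 30
    epochs: int = 50
    optimizer: dict = field(default_factory=dict)
    search_space: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        self.external_seeds = tuple(int(s) for s in self.external_seeds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "base_seed": self.base_seed,
            "external_seeds": list(self.external_seeds),
            "n_folds": self.n_folds,
            "test_fraction": self.test_fraction,
            "population": self.population,
            "epochs": self.epochs,
            "optimizer": self.optimizer,
            "search_space": self.search_space,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# JSON artifacts


def save_fold_outcomes(outcomes: Sequence[FoldOutcome], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([o.to_dict() for o in outcomes], fh, indent=1)


def load_fold_outcomes(path: str | Path) -> list[FoldOutcome]:
    with open(path) as fh:
        return [FoldOutcome.from_dict(d) for d in json.load(fh)]


def save_final_config(config: FinalConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=1)


def load_final_config(path: str | Path) -> FinalConfig:
    with open(path) as fh:
        return FinalConfig.from_dict(json.load(fh))


def save_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
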