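"""Reading and writing of synchronized sEMG + IMU recordings.

Canonical on-disk format is an RFC-4180 CSV with the fixed header
``time_s,emg_mv,acc_x_g,acc_y_g,acc_z_g,gyr_x_dps,gyr_y_dps,gyr_z_dps``
plus a JSON sidecar ``<name>.meta.json`` carrying trial metadata and the
MVC reference.  The time column is derived from the sampling rate and is
not authoritative.  Sample indexing is 0-based; windows are half-open.

The module also ships the published per-condition results table (mean ±
SD of all 11 features for both protocols, both environments, three rep
counts and both arms) as a packaged fixture, exposed through
:func:`load_printed_results`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "Recording",
    "PrintedResultsTable",
    "SchemaError",
    "IntegrityError",
    "read_recording",
    "write_recording",
    "load_printed_results",
    "CSV_COLUMNS",
    "TIME_DOMAIN_FEATURES",
    "FREQUENCY_DOMAIN_FEATURES",
    "IMU_FEATURES",
    "ALL_FEATURES",
]

CSV_COLUMNS = [
    "time_s",
    "emg_mv",
    "acc_x_g",
    "acc_y_g",
    "acc_z_g",
    "gyr_x_dps",
    "gyr_y_dps",
    "gyr_z_dps",
]

META_KEYS = [
    "subject_id",
    "protocol",
    "environment",
    "reps_target",
    "arm",
    "set_index",
    "sampling_rate_hz",
    "mvc_reference_mv",
]

TIME_DOMAIN_FEATURES = ["IEMG", "MAV", "SSI", "RMS", "AAC", "VAR"]
FREQUENCY_DOMAIN_FEATURES = ["MNF", "MDF", "PKF"]
IMU_FEATURES = ["mACC", "mGYR"]
ALL_FEATURES = TIME_DOMAIN_FEATURES + FREQUENCY_DOMAIN_FEATURES + IMU_FEATURES

PROTOCOLS = ("BC", "TK")
ENVIRONMENTS = ("land", "aquatic")
ARMS = ("left", "right")


class SchemaError(ValueError):
    """A file does not match the expected CSV schema."""


class IntegrityError(ValueError):
    """Channels are mutually inconsistent (lengths, time axis, rates)."""


@dataclass
class TimeSeries:
    """A uniformly sampled single channel (unit carried by the label)."""

    samples: np.ndarray
    sampling_rate_hz: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not (self.sampling_rate_hz > 0):
            raise ValueError("sampling_rate_hz must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    def time_axis(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate_hz


@dataclass
class Recording:
    """One trial: sEMG (mV), 3-axis accelerometer (g), 3-axis gyroscope (°/s).

    All channels share one sampling rate and length.  ``annotations`` is an
    optional list of ``(sample_index, label)`` pairs; the synthetic cohort
    uses labels ``"contraction_start"`` and ``"rep_onset"`` to carry the
    protocol timeline and ground-truth movement onsets.
    """

    subject_id: str
    protocol: str
    environment: str
    reps_target: int
    arm: str
    set_index: int
    semg: TimeSeries
    acc: tuple[TimeSeries, TimeSeries, TimeSeries]
    gyr: tuple[TimeSeries, TimeSeries, TimeSeries]
    mvc_reference_mv: float
    annotations: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {PROTOCOLS}")
        if self.environment not in ENVIRONMENTS:
            raise ValueError(f"environment must be one of {ENVIRONMENTS}")
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}")
        if not (self.mvc_reference_mv > 0):
            raise ValueError("mvc_reference_mv must be positive")
        if self.reps_target < 1:
            raise ValueError("reps_target must be >= 1")
        channels = [self.semg, *self.acc, *self.gyr]
        n = len(self.semg)
        fs = self.semg.sampling_rate_hz
        for ch in channels:
            if len(ch) != n:
                raise IntegrityError("all channels must share the same length")
            if ch.sampling_rate_hz != fs:
                raise IntegrityError("all channels must share the sampling rate")

    @property
    def sampling_rate_hz(self) -> float:
        return self.semg.sampling_rate_hz

    @property
    def n_samples(self) -> int:
        return len(self.semg)

    @property
    def trial_key(self) -> str:
        return (
            f"{self.subject_id}_{self.protocol}_{self.environment}"
            f"_r{self.reps_target}_{self.arm}_s{self.set_index}"
        )

    def annotation_indices(self, label: str) -> list[int]:
        return [i for i, lab in self.annotations if lab == label]


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a Recording as CSV + JSON metadata sidecar; returns the CSV path."""
    path = Path(path)
    n = rec.n_samples
    data = {
        "time_s": np.arange(n) / rec.sampling_rate_hz,
        "emg_mv": rec.semg.samples,
        "acc_x_g": rec.acc[0].samples,
        "acc_y_g": rec.acc[1].samples,
        "acc_z_g": rec.acc[2].samples,
        "gyr_x_dps": rec.gyr[0].samples,
        "gyr_y_dps": rec.gyr[1].samples,
        "gyr_z_dps": rec.gyr[2].samples,
    }
    # pandas serializes float64 via repr, which round-trips exactly
    pd.DataFrame(data, columns=CSV_COLUMNS).to_csv(path, index=False)
    meta = {
        "subject_id": rec.subject_id,
        "protocol": rec.protocol,
        "environment": rec.environment,
        "reps_target": rec.reps_target,
        "arm": rec.arm,
        "set_index": rec.set_index,
        "sampling_rate_hz": rec.sampling_rate_hz,
        "mvc_reference_mv": rec.mvc_reference_mv,
        "annotations": [[int(i), lab] for i, lab in rec.annotations],
    }
    meta_path = path.with_suffix(path.suffix + ".meta.json") if path.suffix != ".csv" \
        else path.with_name(path.stem + ".meta.json")
    meta_path.write_text(json.dumps(meta, indent=1))
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a Recording written by :func:`write_recording`."""
    path = Path(path)
    meta_path = path.with_name(path.stem + ".meta.json")
    if not meta_path.exists():
        raise SchemaError(f"missing metadata sidecar: {meta_path}")
    meta = json.loads(meta_path.read_text())
    missing_meta = [k for k in META_KEYS if k not in meta]
    if missing_meta:
        raise SchemaError(f"metadata missing keys: {missing_meta}")

    # round_trip parsing keeps the repr-serialized samples bit-exact
    df = pd.read_csv(path, float_precision="round_trip")
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing column: {col}")
    t = df["time_s"].to_numpy()
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        raise IntegrityError("time_s column is not strictly increasing")

    fs = float(meta["sampling_rate_hz"])

    def ts(col: str) -> TimeSeries:
        return TimeSeries(df[col].to_numpy(), fs, channel_label=col)

    return Recording(
        subject_id=str(meta["subject_id"]),
        protocol=meta["protocol"],
        environment=meta["environment"],
        reps_target=int(meta["reps_target"]),
        arm=meta["arm"],
        set_index=int(meta["set_index"]),
        semg=ts("emg_mv"),
        acc=(ts("acc_x_g"), ts("acc_y_g"), ts("acc_z_g")),
        gyr=(ts("gyr_x_dps"), ts("gyr_y_dps"), ts("gyr_z_dps")),
        mvc_reference_mv=float(meta["mvc_reference_mv"]),
        annotations=[(int(i), str(lab)) for i, lab in meta.get("annotations", [])],
    )


class PrintedResultsTable:
    """The published per-condition feature table (mean ± SD per cell).

    Cells are keyed by (feature, environment, protocol, reps, arm).  The
    table is reproduced verbatim, including its printed duplications (the
    PKF block repeats the MDF block; mACC/mGYR repeat across arms), which
    are flagged rather than resolved.
    """

    def __init__(self, df: pd.DataFrame):
        expected = {"feature", "environment", "protocol", "reps", "arm", "mean", "sd", "unit"}
        if not expected.issubset(df.columns):
            raise SchemaError(f"printed results table missing columns: {expected - set(df.columns)}")
        if (df["sd"] < 0).any():
            raise IntegrityError("printed SDs must be nonnegative")
        self.df = df.copy()
        self._idx = df.set_index(["feature", "environment", "protocol", "reps", "arm"])

    def lookup(self, feature: str, environment: str, protocol: str, reps: int, arm: str) -> tuple[float, float]:
        """Return (mean, sd) for one table cell."""
        row = self._idx.loc[(feature, environment, protocol, int(reps), arm)]
        return float(row["mean"]), float(row["sd"])

    def __len__(self) -> int:
        return len(self.df)

    def duplication_flags(self) -> list[str]:
        """Describe the exact duplications present in the printed table."""
        flags = []
        mdf = self.df[self.df.feature == "MDF"].drop(columns=["feature", "unit"]).reset_index(drop=True)
        pkf = self.df[self.df.feature == "PKF"].drop(columns=["feature", "unit"]).reset_index(drop=True)
        if mdf.equals(pkf):
            flags.append("PKF block identical to MDF block as printed")
        for feat in IMU_FEATURES:
            sub = self.df[self.df.feature == feat]
            left = sub[sub.arm == "left"].drop(columns="arm").reset_index(drop=True)
            right = sub[sub.arm == "right"].drop(columns="arm").reset_index(drop=True)
            if left.equals(right):
                flags.append(f"{feat} identical across arms as printed")
        return flags


def load_printed_results() -> PrintedResultsTable:
    """Load the packaged published results table fixture."""
    with resources.files("aquamyo.data").joinpath("printed_results.csv").open("r") as fh:
        df = pd.read_csv(fh)
    return PrintedResultsTable(df)
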