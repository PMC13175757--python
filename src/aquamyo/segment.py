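"""Acceleration-gated activity segmentation.

The device's acquisition rule is reproduced offline: an increase in
acceleration marks the initiation of a movement, and each activity
window runs from one detected acceleration onset to the next (the final
window is closed at the end of the signal).  The detection threshold is
baseline-relative — rest-stage mean plus ``k_sd`` baseline standard
deviations of the gravity-removed acceleration magnitude — with
debouncing (minimum supra-threshold duration) and a refractory gap
between accepted onsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import IntegrityError, TimeSeries

__all__ = [
    "Segment",
    "acc_magnitude",
    "remove_gravity",
    "detect_activity",
    "segments_to_tsv",
]


@dataclass(frozen=True)
class Segment:
    """Half-open sample window [start, end), 0-based."""

    start: int
    end: int
    label: str = "activity"  # rest | activity

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid segment [{self.start}, {self.end})")
        if self.label not in ("rest", "activity"):
            raise ValueError(f"unknown segment label: {self.label!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def slice(self) -> slice:
        return slice(self.start, self.end)


def acc_magnitude(acc: tuple[TimeSeries, TimeSeries, TimeSeries]) -> TimeSeries:
    """Per-sample Euclidean magnitude of the (gravity-removed) axes."""
    ax, ay, az = acc
    if not (len(ax) == len(ay) == len(az)):
        raise IntegrityError("acceleration axes must have equal lengths")
    mag = np.sqrt(ax.samples**2 + ay.samples**2 + az.samples**2)
    return TimeSeries(mag, ax.sampling_rate_hz, "acc_magnitude")


def remove_gravity(
    acc: tuple[TimeSeries, TimeSeries, TimeSeries], baseline: Segment
) -> tuple[TimeSeries, TimeSeries, TimeSeries]:
    """Subtract the rest-stage mean of each axis (static gravity estimate)."""
    out = []
    for ch in acc:
        if baseline.end > len(ch):
            raise ValueError("baseline extends past the series")
        mean = float(np.mean(ch.samples[baseline.slice()]))
        out.append(TimeSeries(ch.samples - mean, ch.sampling_rate_hz, ch.channel_label))
    return tuple(out)


def detect_activity(
    accmag: TimeSeries,
    baseline: Segment,
    k_sd: float = 3.0,
    min_gap_ms: float = 250.0,
    min_duration_ms: float = 100.0,
    mode: str = "between_onsets",
    max_dropout_ms: float = 20.0,
) -> list[Segment]:
    """Detect activity segments from acceleration-magnitude onsets.

    Threshold = baseline mean + ``k_sd`` × baseline SD.  Sub-threshold
    gaps shorter than ``max_dropout_ms`` inside a movement are bridged
    (hysteresis against momentary dips); onsets are then the first
    samples of supra-threshold runs lasting at least ``min_duration_ms``,
    and onsets closer than ``min_gap_ms`` to the previous accepted onset
    are discarded.  In ``between_onsets`` mode (the device's rule)
    consecutive onsets delimit activity windows and the trailing window
    is closed at the signal end; ``onset_offset`` mode instead emits one
    window per supra-threshold run.
    """
    if mode not in ("between_onsets", "onset_offset"):
        raise ValueError(f"unknown mode: {mode!r}")
    if baseline.end > len(accmag):
        raise ValueError("baseline extends past the series")
    if len(baseline) < 100:
        raise ValueError("baseline must contain at least 100 samples")
    if not (k_sd > 0):
        raise ValueError("k_sd must be positive")

    fs = accmag.sampling_rate_hz
    base = accmag.samples[baseline.slice()]
    threshold = float(np.mean(base) + k_sd * np.std(base, ddof=1))

    min_dur = max(1, int(round(min_duration_ms / 1000.0 * fs)))
    min_gap = int(round(min_gap_ms / 1000.0 * fs))
    max_dropout = int(round(max_dropout_ms / 1000.0 * fs))

    above = accmag.samples >= threshold
    # run starts/ends of consecutive supra-threshold samples
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size]])

    # bridge momentary sub-threshold dips inside a sustained movement;
    # isolated noise blips must not seed a bridge, so the preceding run
    # has to be substantial before a gap is closed
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if (
            merged
            and s - merged[-1][1] <= max_dropout
            and merged[-1][1] - merged[-1][0] >= max_dropout
        ):
            merged[-1][1] = e
        else:
            merged.append([int(s), int(e)])
    runs = [(s, e) for s, e in merged if e - s >= min_dur]

    onsets: list[int] = []
    run_ends: list[int] = []
    for s, e in runs:
        if onsets and s - onsets[-1] < min_gap:
            run_ends[-1] = e  # debounce: extend the current movement
            continue
        onsets.append(int(s))
        run_ends.append(int(e))

    if not onsets:
        return []

    if mode == "onset_offset":
        return [Segment(s, e, "activity") for s, e in zip(onsets, run_ends)]

    bounds = onsets + [len(accmag)]
    return [Segment(bounds[i], bounds[i + 1], "activity") for i in range(len(onsets))]


def segments_to_tsv(segments: list[Segment], path) -> None:
    """Write segments as a 3-column TSV (start, end, label) in sample coords."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.start}\t{seg.end}\t{seg.label}\n")
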