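"""End-to-end composition: recording → segments → features → tables.

Features are computed per activity segment (one segment per repetition,
delimited by consecutive acceleration onsets) and averaged per trial;
the long-format feature table keys rows by subject / protocol /
environment / reps / arm / set, matching how per-condition means ± SDs
are reported.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .features import (
    FeatureVector,
    frequency_domain_features,
    imu_features,
    power_spectrum,
    time_domain_features,
)
from .io import ALL_FEATURES, IMU_FEATURES, Recording, TimeSeries
from .preprocess import ACC_BANDPASS, SEMG_BANDPASS, FilterSpec, filter_series, normalize_mvc
from .segment import Segment, acc_magnitude, detect_activity, remove_gravity

__all__ = [
    "rest_baseline",
    "segment_recording",
    "extract_features",
    "process_cohort",
    "long_format",
]

UNITS = {
    "IEMG": "mvc_fraction", "MAV": "mvc_fraction", "SSI": "mvc_fraction^2",
    "RMS": "mvc_fraction", "AAC": "mvc_fraction", "VAR": "mvc_fraction^2",
    "MNF": "Hz", "MDF": "Hz", "PKF": "Hz", "mACC": "g", "mGYR": "deg/s",
}


def rest_baseline(rec: Recording, default_fraction: float = 0.2) -> Segment:
    """The rest-stage window: from the timeline annotation when present,
    otherwise the leading fraction of the recording."""
    marks = rec.annotation_indices("contraction_start")
    end = marks[0] if marks else int(default_fraction * rec.n_samples)
    return Segment(0, max(end, 1), "rest")


def segment_recording(rec: Recording, cfg: PipelineConfig) -> tuple[list[Segment], tuple, tuple]:
    """Detect activity segments; returns (segments, acc_nog, gyr_nog).

    Gravity (and any gyroscope bias) is removed with the configured
    strategy before magnitudes are formed.
    """
    baseline = rest_baseline(rec)
    if cfg.preprocessing.gravity_removal == "bandpass":
        spec = FilterSpec("bandpass", *cfg.preprocessing.acc_band_hz,
                          order=cfg.preprocessing.filter_order)
        acc_nog = tuple(filter_series(ch, spec) for ch in rec.acc)
        gyr_nog = tuple(filter_series(ch, spec) for ch in rec.gyr)
    else:
        acc_nog = remove_gravity(rec.acc, baseline)
        gyr_nog = remove_gravity(rec.gyr, baseline)
    accmag = acc_magnitude(acc_nog)
    segs = detect_activity(
        accmag,
        baseline,
        k_sd=cfg.segmentation.k_sd,
        min_gap_ms=cfg.segmentation.min_gap_ms,
        min_duration_ms=cfg.segmentation.min_duration_ms,
        mode=cfg.segmentation.mode,
    )
    return segs, acc_nog, gyr_nog


def extract_features(rec: Recording, cfg: PipelineConfig | None = None) -> tuple[dict, dict]:
    """One trial → (feature row, segmentation diagnostics).

    The feature row holds the 11 quantities averaged over the trial's
    activity segments plus the trial key columns; diagnostics compare
    detected onsets with the ground-truth annotations when present.
    """
    cfg = cfg or PipelineConfig()
    segs, acc_nog, gyr_nog = segment_recording(rec, cfg)

    semg = filter_series(
        rec.semg,
        FilterSpec("bandpass", *cfg.preprocessing.semg_band_hz,
                   order=cfg.preprocessing.filter_order,
                   zero_phase=cfg.preprocessing.zero_phase),
    )
    semg = normalize_mvc(semg, rec.mvc_reference_mv)

    per_segment: list[FeatureVector] = []
    for seg in segs:
        x = TimeSeries(semg.samples[seg.slice()], semg.sampling_rate_hz, "semg_mvc")
        iemg, mav, ssi, rms, aac, var = time_domain_features(x)
        S = power_spectrum(x, window_ms=cfg.features.welch_window_ms,
                           overlap_fraction=cfg.features.welch_overlap)
        mnf, mdf, pkf = frequency_domain_features(S, band_hz=cfg.features.band_hz)
        macc, mgyr = imu_features(acc_nog, gyr_nog, seg, statistic=cfg.features.imu_statistic)
        per_segment.append(FeatureVector(iemg, mav, ssi, rms, aac, var, mnf, mdf, pkf, macc, mgyr))

    row = {
        "subject_id": rec.subject_id,
        "protocol": rec.protocol,
        "environment": rec.environment,
        "reps": rec.reps_target,
        "arm": rec.arm,
        "set": rec.set_index,
        "n_segments": len(per_segment),
    }
    for name in ALL_FEATURES:
        row[name] = float(np.mean([getattr(fv, name) for fv in per_segment])) if per_segment else np.nan

    truth = rec.annotation_indices("rep_onset")
    diag = {
        "subject_id": rec.subject_id,
        "protocol": rec.protocol,
        "environment": rec.environment,
        "reps": rec.reps_target,
        "set": rec.set_index,
        "n_true": len(truth),
        "n_detected": len(segs),
    }
    if truth and segs:
        onsets = np.array([s.start for s in segs], dtype=float)
        errors_ms = [
            abs(onsets[np.argmin(np.abs(onsets - t))] - t) / rec.sampling_rate_hz * 1000.0
            for t in truth
        ]
        diag["max_onset_error_ms"] = float(max(errors_ms))
        diag["mean_onset_error_ms"] = float(np.mean(errors_ms))
    else:
        diag["max_onset_error_ms"] = np.nan
        diag["mean_onset_error_ms"] = np.nan
    return row, diag


def process_cohort(
    recordings: Iterable[Recording], cfg: PipelineConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stream recordings through the pipeline.

    Returns (wide per-trial feature table, per-trial segmentation
    diagnostics).  Recordings are materialized one at a time so full
    cohorts never reside in memory.
    """
    cfg = cfg or PipelineConfig()
    rows, diags = [], []
    for rec in recordings:
        row, diag = extract_features(rec, cfg)
        rows.append(row)
        diags.append(diag)
    return pd.DataFrame(rows), pd.DataFrame(diags)


def long_format(wide: pd.DataFrame) -> pd.DataFrame:
    """Wide per-trial table → long format (one row per trial × feature)."""
    keys = ["subject_id", "protocol", "environment", "reps", "arm", "set"]
    long = wide.melt(id_vars=keys, value_vars=list(ALL_FEATURES),
                     var_name="feature", value_name="value")
    long["unit"] = long["feature"].map(UNITS)
    return long
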