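"""Filtering, MVC normalization and rectified-RMS envelope computation.

The sEMG band defaults to 20–450 Hz (standard surface-EMG practice) and
the accelerometer band to 0.3–15 Hz, which removes the gravitational DC
component together with high-frequency noise.  Filters are zero-phase by
default (forward-backward second-order sections), so onsets are not
delayed.  Envelope windows are truncated at the signal boundaries rather
than padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import TimeSeries

__all__ = [
    "FilterSpec",
    "SEMG_BANDPASS",
    "ACC_BANDPASS",
    "filter_series",
    "normalize_mvc",
    "rms_envelope",
    "mvc_reference",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter description."""

    kind: str  # bandpass | highpass | lowpass
    low_hz: float = 0.0
    high_hz: float = 0.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "highpass", "lowpass"):
            raise ValueError(f"unknown filter kind: {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.kind == "bandpass" and not (0 <= self.low_hz < self.high_hz):
            raise ValueError("bandpass requires 0 <= low_hz < high_hz")

    def sos(self, fs: float) -> np.ndarray:
        nyq = fs / 2.0
        if self.kind == "bandpass":
            if self.high_hz >= nyq:
                raise ValueError(f"high cutoff {self.high_hz} Hz >= Nyquist {nyq} Hz")
            wn = (self.low_hz / nyq, self.high_hz / nyq)
            btype = "bandpass"
        elif self.kind == "highpass":
            if self.low_hz >= nyq:
                raise ValueError(f"cutoff {self.low_hz} Hz >= Nyquist {nyq} Hz")
            wn = self.low_hz / nyq
            btype = "highpass"
        else:
            if self.high_hz >= nyq:
                raise ValueError(f"cutoff {self.high_hz} Hz >= Nyquist {nyq} Hz")
            wn = self.high_hz / nyq
            btype = "lowpass"
        return sps.butter(self.order, wn, btype=btype, output="sos")


SEMG_BANDPASS = FilterSpec("bandpass", 20.0, 450.0, order=4)
ACC_BANDPASS = FilterSpec("bandpass", 0.3, 15.0, order=4)


def filter_series(ts: TimeSeries, spec: FilterSpec) -> TimeSeries:
    """Apply a FilterSpec; same length and rate, zero-phase when requested."""
    sos = spec.sos(ts.sampling_rate_hz)
    if spec.zero_phase:
        padlen = 3 * (2 * sos.shape[0] + 1)
        if len(ts) <= padlen:
            raise ValueError(
                f"series too short to filter: {len(ts)} samples <= padlen {padlen}"
            )
        y = sps.sosfiltfilt(sos, ts.samples)
    else:
        if len(ts) < 2:
            raise ValueError("series too short to filter")
        y = sps.sosfilt(sos, ts.samples)
    return TimeSeries(y, ts.sampling_rate_hz, ts.channel_label)


def normalize_mvc(semg: TimeSeries, mvc_reference_mv: float) -> TimeSeries:
    """Scale sEMG to a fraction of the maximal voluntary contraction.

    Division is linear and invertible; the rectified-RMS of a true MVC
    window maps to 1 by construction of the reference.
    """
    if not (mvc_reference_mv > 0):
        raise ValueError("mvc_reference_mv must be positive")
    return TimeSeries(
        semg.samples / mvc_reference_mv, semg.sampling_rate_hz,
        f"{semg.channel_label}_mvc" if semg.channel_label else "mvc_fraction",
    )


def _sliding_rms(x: np.ndarray, window: int, hop: int) -> np.ndarray:
    """RMS over centered windows at every hop, truncated at the boundaries."""
    sq = np.concatenate([[0.0], np.cumsum(x * x)])
    centers = np.arange(0, x.size, hop)
    half = window // 2
    lo = np.clip(centers - half, 0, x.size)
    hi = np.clip(centers - half + window, 0, x.size)
    return np.sqrt((sq[hi] - sq[lo]) / (hi - lo))


def rms_envelope(semg: TimeSeries, window_ms: float = 100.0, hop_ms: float = 10.0) -> TimeSeries:
    """Rectified sliding-RMS envelope (rectification is implicit in squaring).

    Output rate is ``1000 / hop_ms`` Hz.  Constant input ``c`` maps to the
    constant ``|c|``; the envelope is invariant to sign flips.
    """
    window = int(round(window_ms / 1000.0 * semg.sampling_rate_hz))
    hop = max(1, int(round(hop_ms / 1000.0 * semg.sampling_rate_hz)))
    if window < 2:
        raise ValueError("window must span at least 2 samples")
    if window > len(semg):
        raise ValueError("window longer than signal")
    env = _sliding_rms(semg.samples, window, hop)
    return TimeSeries(env, semg.sampling_rate_hz / hop, "rms_envelope")


def mvc_reference(semg: TimeSeries, window_ms: float = 500.0) -> float:
    """MVC reference: peak 500 ms rectified-RMS during a designated MVC trial.

    Only fully covered windows enter the maximum, so boundary truncation
    cannot inflate the reference.  Like any max-of-estimates statistic it
    carries a modest upward bias on stationary signals.
    """
    window = int(round(window_ms / 1000.0 * semg.sampling_rate_hz))
    hop = max(1, window // 10)
    if window < 2 or window > len(semg):
        raise ValueError("MVC window must span 2..n samples")
    x = semg.samples
    sq = np.concatenate([[0.0], np.cumsum(x * x)])
    lo = np.arange(0, x.size - window + 1, hop)
    rms = np.sqrt((sq[lo + window] - sq[lo]) / window)
    return float(np.max(rms))
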