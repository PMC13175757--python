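"""The 11 sEMG/IMU features and their published normal ranges.

Time domain (on the MVC-normalized sEMG of one activity segment, length N):

    IEMG = Σ|x_i|            MAV = IEMG / N         SSI = Σ x_i²
    RMS  = √(SSI / N)        AAC = (1/N) Σ_{i<N} |x_{i+1} − x_i|
    VAR  = SSI / (N − 1)     (zero-mean convention, no mean subtraction)

Note the AAC prefactor is 1/N over N−1 terms, and VAR divides the raw
energy by N−1; both follow the published definitions.

Frequency domain (on a Welch one-sided PSD with frequencies f_j, powers P_j):

    MNF = Σ f_j P_j / Σ P_j
    MDF = frequency splitting the spectral mass in half (linearly
          interpolated inside the crossing bin, bin mass at bin center)
    PKF = frequency of the maximum bin (lowest frequency on ties)

IMU: mACC / mGYR are the segment means of the per-sample Euclidean
magnitude of the gravity-removed accelerometer / gyroscope axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import TimeSeries
from .segment import Segment, acc_magnitude

__all__ = [
    "SpectralEstimate",
    "FeatureVector",
    "NORMAL_RANGES",
    "time_domain_features",
    "power_spectrum",
    "frequency_domain_features",
    "imu_features",
    "range_check",
]

# Published normal ranges per feature (units as in the feature table).
NORMAL_RANGES: dict[str, tuple[float, float]] = {
    "IEMG": (700.0, 900.0),
    "MAV": (0.1, 0.4),
    "SSI": (200.0, 350.0),
    "RMS": (0.1, 0.5),
    "AAC": (0.01, 0.1),
    "VAR": (0.01, 0.1),
    "MNF": (40.0, 100.0),
    "MDF": (40.0, 100.0),
    "PKF": (40.0, 100.0),
    "mACC": (1.0, 6.0),
    "mGYR": (0.0, 100.0),
}


@dataclass
class SpectralEstimate:
    """One-sided power spectral density estimate."""

    f: np.ndarray
    P: np.ndarray
    resolution_hz: float

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.f.shape != self.P.shape:
            raise ValueError("f and P must have the same shape")
        if np.any(self.P < 0):
            raise ValueError("power values must be nonnegative")
        if self.f.size >= 2 and np.any(np.diff(self.f) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    def band(self, low_hz: float, high_hz: float) -> "SpectralEstimate":
        mask = (self.f >= low_hz) & (self.f <= high_hz)
        if not np.any(mask):
            raise ValueError(f"band [{low_hz}, {high_hz}] Hz contains no bins")
        return SpectralEstimate(self.f[mask], self.P[mask], self.resolution_hz)


@dataclass
class FeatureVector:
    """The 11 per-segment quantities (units: mV, mV², Hz, g, °/s)."""

    IEMG: float
    MAV: float
    SSI: float
    RMS: float
    AAC: float
    VAR: float
    MNF: float
    MDF: float
    PKF: float
    mACC: float
    mGYR: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in NORMAL_RANGES}


def time_domain_features(x: TimeSeries | np.ndarray) -> tuple[float, float, float, float, float, float]:
    """(IEMG, MAV, SSI, RMS, AAC, VAR) of one segment; requires N >= 2."""
    arr = x.samples if isinstance(x, TimeSeries) else np.asarray(x, dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError("time-domain features require at least 2 samples")
    iemg = float(np.sum(np.abs(arr)))
    ssi = float(np.sum(arr * arr))
    return (
        iemg,
        iemg / n,
        ssi,
        float(np.sqrt(ssi / n)),
        float(np.sum(np.abs(np.diff(arr))) / n),
        ssi / (n - 1),
    )


def power_spectrum(
    x: TimeSeries, window_ms: float = 256.0, overlap_fraction: float = 0.5
) -> SpectralEstimate:
    """Welch-averaged one-sided PSD (Hann window)."""
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must be in [0, 1)")
    fs = x.sampling_rate_hz
    nperseg = int(round(window_ms / 1000.0 * fs))
    noverlap = int(round(nperseg * overlap_fraction))
    hop = nperseg - noverlap
    if nperseg < 8 or len(x) < nperseg + hop:
        raise ValueError(
            f"segment of {len(x)} samples too short for {window_ms} ms Welch windows"
        )
    f, P = sps.welch(x.samples, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap)
    return SpectralEstimate(f, P, resolution_hz=fs / nperseg)


def frequency_domain_features(
    S: SpectralEstimate, band_hz: tuple[float, float] | None = None
) -> tuple[float, float, float]:
    """(MNF, MDF, PKF) from a spectral estimate, optionally band-limited."""
    if band_hz is not None:
        S = S.band(*band_hz)
    f, P = S.f, S.P
    total = float(np.sum(P))
    if total <= 0:
        raise ValueError("all-zero spectrum: frequency features undefined")

    mnf = float(np.sum(f * P) / total)

    # MDF: each bin's mass sits at its center; interpolate inside the
    # crossing bin so a single line yields exactly its own frequency.
    c = np.cumsum(P)
    half = total / 2.0
    j = int(np.searchsorted(c, half))
    prev = c[j - 1] if j > 0 else 0.0
    frac = (half - prev) / P[j] if P[j] > 0 else 0.5
    df = float(f[1] - f[0]) if f.size > 1 else S.resolution_hz
    mdf = float(f[j] + (frac - 0.5) * df)

    pkf = float(f[int(np.argmax(P))])  # argmax returns the lowest index on ties
    return mnf, mdf, pkf


def imu_features(
    acc: tuple[TimeSeries, TimeSeries, TimeSeries],
    gyr: tuple[TimeSeries, TimeSeries, TimeSeries],
    seg: Segment,
    statistic: str = "mean",
) -> tuple[float, float]:
    """(mACC, mGYR) over a segment of gravity-removed traces."""
    if statistic not in ("mean", "peak"):
        raise ValueError(f"unknown statistic: {statistic!r}")
    if seg.end > len(acc[0]) or seg.end > len(gyr[0]):
        raise ValueError("segment extends past the series")
    reduce = np.mean if statistic == "mean" else np.max
    macc = float(reduce(acc_magnitude(acc).samples[seg.slice()]))
    mgyr = float(reduce(acc_magnitude(gyr).samples[seg.slice()]))
    return macc, mgyr


def range_check(fv: FeatureVector) -> list[str]:
    """Names of features outside their published normal range; never raises."""
    flags = []
    for name, (lo, hi) in NORMAL_RANGES.items():
        v = getattr(fv, name)
        if not (lo <= v <= hi):
            flags.append(name)
    return flags
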