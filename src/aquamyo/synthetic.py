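"""Synthetic sEMG + IMU cohorts with the statistical structure the analysis assumes.

The sEMG model is band-limited Gaussian noise: white noise is shaped in
the frequency domain by a Gaussian magnitude profile (so the power
spectrum is Gaussian around a controllable center frequency — the mean
and median frequency are then directly controllable), normalized to unit
RMS, and multiplied by a per-repetition trapezoidal envelope whose
plateau RMS equals the requested amplitude.

Each trial follows the exercise timeline: a resting stage (baseline for
gravity estimation and onset thresholds) followed by a 30 s isotonic
contraction stage containing the target number of repetitions.  Each
repetition's limb movement is a rotating acceleration vector — biphasic
per axis (flexion then extension) with a single half-sine magnitude hump
— with a matched angular-rate pulse, a constant 1 g gravity component on
the z axis, and additive sensor noise.  True movement onsets are stored
as recording annotations and in the cohort manifest.

Cohort structure: per-subject amplitude and spectral-center effects are
shared across both environments (so land and aquatic measurements of a
subject are correlated, as the ICC assumes); aquatic recordings are
amplified by ``1 + aquatic_amplitude_gain``, spectrally shifted upward
by ``aquatic_spectral_shift_hz``, and their motion pulses scaled by
``aquatic_acc_scale``.  Class-effect defaults (activation fraction,
spectral offsets, pulse peaks per protocol × rep count) mirror the
published per-condition levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .io import Recording, TimeSeries

__all__ = [
    "GeneratorConfig",
    "SubjectProfile",
    "TrialSpec",
    "ImuTrace",
    "Cohort",
    "generate_semg_burst",
    "trapezoid_envelope",
    "generate_imu_trace",
    "generate_cohort",
]


@dataclass
class GeneratorConfig:
    """All knobs of the cohort generator (defaults are the study conditions)."""

    sampling_rate_hz: float = 1000.0
    rest_duration_s: float = 30.0  # stand-in for the 5-min resting stage
    contraction_duration_s: float = 30.0
    reps_options: tuple[int, ...] = (3, 6, 9)
    n_sets: int = 5
    semg_base_amplitude_mv: float = 1.1  # nominal MVC-level RMS amplitude
    spectral_center_hz: float = 80.0
    spectral_bandwidth_hz: float = 25.0
    aquatic_amplitude_gain: float = 0.15
    aquatic_spectral_shift_hz: float = 20.0
    aquatic_acc_scale: float = 0.95
    between_subject_sd: float = 0.05
    within_subject_sd: float = 0.03
    noise_floor_mv: float = 0.02
    seed: int = 0

    # class effects mirroring the published per-condition levels
    activation_by_class: dict = field(
        default_factory=lambda: {
            ("BC", 3): 0.41, ("BC", 6): 0.36, ("BC", 9): 0.33,
            ("TK", 3): 0.33, ("TK", 6): 0.29, ("TK", 9): 0.27,
        }
    )
    protocol_spectral_offset_hz: dict = field(
        default_factory=lambda: {"BC": 0.0, "TK": -8.0}
    )
    reps_spectral_offset_hz: dict = field(
        default_factory=lambda: {3: 0.0, 6: 12.0, 9: 20.0}
    )
    peak_acc_by_reps: dict = field(
        default_factory=lambda: {3: 3.1, 6: 3.9, 9: 8.7}
    )
    peak_gyr_by_reps: dict = field(
        default_factory=lambda: {3: 48.0, 6: 110.0, 9: 213.0}
    )
    protocol_motion_scale: dict = field(
        default_factory=lambda: {"BC": 1.0, "TK": 1.1}
    )

    # within-trial shape parameters
    motion_fraction: float = 0.7  # fraction of each rep slot spent moving
    envelope_rise_fraction: float = 0.1
    fatigue_decay: float = 0.05  # linear amplitude decay across a set's reps
    subject_spectral_sd_hz: float = 1.0
    within_spectral_sd_hz: float = 1.5
    motion_jitter_sd: float = 0.05
    acc_noise_g: float = 0.02
    gyr_noise_dps: float = 1.0
    arm: str = "right"

    def __post_init__(self) -> None:
        if not (self.rest_duration_s > 0 and self.contraction_duration_s > 0):
            raise ValueError("rest and contraction durations must be positive")
        if len(self.reps_options) == 0:
            raise ValueError("reps_options must be nonempty")
        if any(r < 1 for r in self.reps_options):
            raise ValueError("reps_options must be positive integers")
        if self.aquatic_amplitude_gain < 0:
            raise ValueError("aquatic_amplitude_gain must be nonnegative")
        if not (0 < self.aquatic_acc_scale <= 1):
            raise ValueError("aquatic_acc_scale must be in (0, 1]")
        for name in ("between_subject_sd", "within_subject_sd", "noise_floor_mv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        nyq = self.sampling_rate_hz / 2.0
        top = (
            self.spectral_center_hz
            + max(self.aquatic_spectral_shift_hz, 0)
            + max(self.reps_spectral_offset_hz.values())
            + 3 * self.spectral_bandwidth_hz
        )
        if top >= nyq:
            raise ValueError(
                f"spectral content up to {top:.0f} Hz exceeds Nyquist {nyq:.0f} Hz"
            )


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject effects shared across environments and protocols."""

    subject_id: str
    amplitude_factor: float  # relative submaximal activation, ~1 ± between_subject_sd
    spectral_offset_hz: float
    mvc_amplitude_mv: float

    def __post_init__(self) -> None:
        if not (self.amplitude_factor > 0):
            raise ValueError("amplitude_factor must be positive")


@dataclass(frozen=True)
class TrialSpec:
    """Metadata of one cohort trial (manifest entry)."""

    subject_index: int
    subject_id: str
    protocol: str
    environment: str
    reps: int
    set_index: int
    arm: str


@dataclass
class ImuTrace:
    """3-axis accelerometer + gyroscope with ground-truth onsets (samples)."""

    acc: tuple[TimeSeries, TimeSeries, TimeSeries]
    gyr: tuple[TimeSeries, TimeSeries, TimeSeries]
    onsets: np.ndarray


def _shaped_noise(n: int, fs: float, center_hz: float, bandwidth_hz: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise with a Gaussian-shaped one-sided spectrum."""
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    # amplitude profile; squaring gives the Gaussian power profile
    profile = np.exp(-((f - center_hz) ** 2) / (4.0 * bandwidth_hz**2))
    shaped = np.fft.irfft(np.fft.rfft(white) * profile, n)
    shaped -= shaped.mean()
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms


def generate_semg_burst(
    duration_s: float,
    fs: float,
    amplitude_mv: float,
    center_hz: float,
    bandwidth_hz: float,
    envelope: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> TimeSeries:
    """Amplitude-modulated, spectrally shaped Gaussian noise (mV).

    The plateau (envelope = 1) RMS equals ``amplitude_mv``; the one-sided
    power spectrum is Gaussian around ``center_hz`` with scale
    ``bandwidth_hz``.
    """
    if not (duration_s > 0):
        raise ValueError("duration_s must be positive")
    if not (fs > 0):
        raise ValueError("fs must be positive")
    if amplitude_mv < 0:
        raise ValueError("amplitude_mv must be nonnegative")
    if center_hz + 3 * bandwidth_hz >= fs / 2:
        raise ValueError(
            f"spectral band {center_hz}±3×{bandwidth_hz} Hz exceeds Nyquist {fs / 2} Hz"
        )
    n = int(round(duration_s * fs))
    if n < 64:
        raise ValueError("burst must span at least 64 samples")
    rng = np.random.default_rng() if rng is None else rng
    if amplitude_mv == 0.0:
        rng.standard_normal(n)  # keep the stream position deterministic
        return TimeSeries(np.zeros(n), fs, "semg_mv")
    noise = _shaped_noise(n, fs, center_hz, bandwidth_hz, rng)
    if envelope is None:
        env = 1.0
    else:
        env = np.asarray(envelope, dtype=float)
        if env.shape != (n,):
            raise ValueError(f"envelope length {env.size} != {n} samples")
    return TimeSeries(amplitude_mv * env * noise, fs, "semg_mv")


def trapezoid_envelope(
    n: int,
    reps: int,
    active_fraction: float = 0.7,
    rise_fraction: float = 0.1,
    fatigue_decay: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-rep trapezoidal envelope over ``n`` samples; returns (envelope, onsets).

    Each of ``reps`` equal slots holds one activation burst occupying
    ``active_fraction`` of the slot from the slot start, with linear
    rise/fall ramps of ``rise_fraction`` of the burst each.  Plateau
    height is 1 for the first rep, decaying linearly by ``fatigue_decay``
    across the set.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    slot = n // reps
    active = int(round(active_fraction * slot))
    ramp = max(1, int(round(rise_fraction * active)))
    if active < 2 * ramp:
        raise ValueError("slots too short for the requested envelope")
    env = np.zeros(n)
    onsets = np.zeros(reps, dtype=int)
    for r in range(reps):
        start = r * slot
        scale = 1.0 - (fatigue_decay * r / (reps - 1) if reps > 1 else 0.0)
        shape = np.ones(active)
        shape[:ramp] = np.linspace(0.0, 1.0, ramp, endpoint=False)
        shape[active - ramp:] = np.linspace(1.0, 0.0, ramp)
        env[start:start + active] = scale * shape
        onsets[r] = start
    return env, onsets


def generate_imu_trace(
    reps: int,
    window_s: float,
    fs: float,
    peak_acc_g: float = 3.0,
    peak_gyr_dps: float = 60.0,
    env_scale: float = 1.0,
    rng: np.random.Generator | None = None,
    motion_fraction: float = 0.7,
    acc_noise_g: float = 0.0,
    gyr_noise_dps: float = 0.0,
    gravity_axis: str = "z",
    onset_spike_ms: float = 100.0,
    onset_spike_fraction: float = 0.5,
) -> ImuTrace:
    """Per-rep movement pulses with gravity, noise, and ground-truth onsets.

    Each rep's acceleration is a rotating vector in the x–y plane with
    magnitude ``p·sin(πt/L)`` and direction angle sweeping 0→π over the
    movement, so each axis is biphasic (flexion then extension) while
    the gravity-removed magnitude has one dominant hump per rep.  A
    brief jerk transient (``onset_spike_ms`` half-sine at
    ``onset_spike_fraction`` of the peak) marks movement initiation, as
    abrupt load changes do in real limb movement.  ``env_scale``
    multiplies all pulse magnitudes (aquatic drag reduces movement
    vigor).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not (0 < env_scale <= 1):
        raise ValueError("env_scale must be in (0, 1]")
    n = int(round(window_s * fs))
    if n < reps * 16:
        raise ValueError(f"window of {n} samples infeasible for {reps} reps")
    slot = n // reps
    motion = int(round(motion_fraction * slot))
    if motion < 4:
        raise ValueError("rep slots too short for a movement pulse")
    rng = np.random.default_rng() if rng is None else rng

    acc = np.zeros((3, n))
    gyr = np.zeros((3, n))
    onsets = np.zeros(reps, dtype=int)
    t = np.arange(motion) / motion  # 0 .. 1 over one movement
    mag = np.sin(np.pi * t)  # single dominant hump
    angle = np.pi * t  # flexion -> extension direction sweep
    px, py = mag * np.cos(angle), mag * np.sin(angle)
    spike_len = min(int(round(onset_spike_ms / 1000.0 * fs)), motion // 2)
    if spike_len >= 2 and onset_spike_fraction > 0:
        spike = onset_spike_fraction * np.sin(np.pi * np.arange(spike_len) / spike_len)
        px = px.copy()
        px[:spike_len] += spike  # jerk along the initial movement direction
    for r in range(reps):
        start = r * slot
        onsets[r] = start
        acc[0, start:start + motion] += env_scale * peak_acc_g * px
        acc[1, start:start + motion] += env_scale * peak_acc_g * py
        gyr[0, start:start + motion] += env_scale * peak_gyr_dps * px
        gyr[1, start:start + motion] += env_scale * peak_gyr_dps * py

    axis_index = {"x": 0, "y": 1, "z": 2}[gravity_axis]
    acc[axis_index] += 1.0  # static gravity
    if acc_noise_g > 0:
        acc += acc_noise_g * rng.standard_normal((3, n))
    if gyr_noise_dps > 0:
        gyr += gyr_noise_dps * rng.standard_normal((3, n))

    def pack(arr: np.ndarray, labels: Sequence[str]) -> tuple[TimeSeries, ...]:
        return tuple(TimeSeries(arr[i], fs, lab) for i, lab in enumerate(labels))

    return ImuTrace(
        acc=pack(acc, ("acc_x_g", "acc_y_g", "acc_z_g")),
        gyr=pack(gyr, ("gyr_x_dps", "gyr_y_dps", "gyr_z_dps")),
        onsets=onsets,
    )


class Cohort:
    """Lazy collection of Recordings; trials regenerate deterministically.

    Per-recording random streams are derived from the master seed by
    counter-based key splitting (``SeedSequence`` spawn keys), so any
    trial can be materialized independently and cohorts are bit-identical
    across runs and iteration orders.
    """

    def __init__(self, n_subjects: int, config: GeneratorConfig):
        if n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        self.config = config
        self.subjects = [self._make_profile(i) for i in range(n_subjects)]
        self.trials: list[TrialSpec] = [
            TrialSpec(i, self.subjects[i].subject_id, proto, env, reps, s + 1, config.arm)
            for i in range(n_subjects)
            for proto in ("BC", "TK")
            for env in ("land", "aquatic")
            for reps in config.reps_options
            for s in range(config.n_sets)
        ]

    def _make_profile(self, i: int) -> SubjectProfile:
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101, i]))
        amp = 1.0 + cfg.between_subject_sd * rng.standard_normal()
        spec = cfg.subject_spectral_sd_hz * rng.standard_normal()
        mvc = cfg.semg_base_amplitude_mv * (
            1.0 + cfg.between_subject_sd * abs(rng.standard_normal())
        )
        return SubjectProfile(
            subject_id=f"S{i + 1:02d}",
            amplitude_factor=max(0.2, amp),
            spectral_offset_hz=spec,
            mvc_amplitude_mv=mvc,
        )

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[Recording]:
        for trial in self.trials:
            yield self.materialize(trial)

    def materialize(self, trial: TrialSpec) -> Recording:
        cfg = self.config
        prof = self.subjects[trial.subject_index]
        proto_i = ("BC", "TK").index(trial.protocol)
        env_i = ("land", "aquatic").index(trial.environment)
        reps_i = list(cfg.reps_options).index(trial.reps)
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [cfg.seed, 202, trial.subject_index, proto_i, env_i, reps_i, trial.set_index]
            )
        )
        fs = cfg.sampling_rate_hz
        n_rest = int(round(cfg.rest_duration_s * fs))
        n_con = int(round(cfg.contraction_duration_s * fs))
        aquatic = trial.environment == "aquatic"

        amp_jitter = max(0.1, 1.0 + cfg.within_subject_sd * rng.standard_normal())
        spec_jitter = cfg.within_spectral_sd_hz * rng.standard_normal()
        motion_jitter = max(0.1, 1.0 + cfg.motion_jitter_sd * rng.standard_normal())

        # class-effect dicts are keyed by the canonical rep counts; custom
        # reps_options fall back to the nearest tabulated class
        def by_reps(d: dict, reps: int) -> float:
            if reps in d:
                return d[reps]
            return d[min(d, key=lambda k: abs(k - reps))]

        activation = cfg.activation_by_class
        key = (trial.protocol, trial.reps)
        if key not in activation:
            sub = {r: v for (p, r), v in activation.items() if p == trial.protocol}
            act = by_reps(sub, trial.reps)
        else:
            act = activation[key]

        plateau_rms = (
            prof.mvc_amplitude_mv
            * act
            * prof.amplitude_factor
            * (1.0 + cfg.aquatic_amplitude_gain if aquatic else 1.0)
            * amp_jitter
        )
        center = (
            cfg.spectral_center_hz
            + prof.spectral_offset_hz
            + cfg.protocol_spectral_offset_hz[trial.protocol]
            + by_reps(cfg.reps_spectral_offset_hz, trial.reps)
            + (cfg.aquatic_spectral_shift_hz if aquatic else 0.0)
            + spec_jitter
        )

        env, _ = trapezoid_envelope(
            n_con, trial.reps,
            active_fraction=cfg.motion_fraction,
            rise_fraction=cfg.envelope_rise_fraction,
            fatigue_decay=cfg.fatigue_decay,
        )
        burst = generate_semg_burst(
            cfg.contraction_duration_s, fs, plateau_rms, center,
            cfg.spectral_bandwidth_hz, envelope=env, rng=rng,
        )
        semg = np.concatenate([np.zeros(n_rest), burst.samples])
        semg += cfg.noise_floor_mv * rng.standard_normal(semg.size)

        motion_scale = cfg.protocol_motion_scale[trial.protocol] * motion_jitter
        imu = generate_imu_trace(
            trial.reps, cfg.contraction_duration_s, fs,
            peak_acc_g=by_reps(cfg.peak_acc_by_reps, trial.reps) * motion_scale,
            peak_gyr_dps=by_reps(cfg.peak_gyr_by_reps, trial.reps) * motion_scale,
            env_scale=cfg.aquatic_acc_scale if aquatic else 1.0,
            rng=rng,
            motion_fraction=cfg.motion_fraction,
            acc_noise_g=0.0,  # noise added over the full trial below
            gyr_noise_dps=0.0,
        )
        acc = np.zeros((3, n_rest + n_con))
        gyr = np.zeros((3, n_rest + n_con))
        acc[2] += 1.0  # gravity on z throughout, rest included
        for i in range(3):
            acc[i, n_rest:] += imu.acc[i].samples - (1.0 if i == 2 else 0.0)
            gyr[i, n_rest:] += imu.gyr[i].samples
        acc += cfg.acc_noise_g * rng.standard_normal(acc.shape)
        gyr += cfg.gyr_noise_dps * rng.standard_normal(gyr.shape)

        onsets = (imu.onsets + n_rest).tolist()
        annotations = [(0, "rest_start"), (n_rest, "contraction_start")]
        annotations += [(int(o), "rep_onset") for o in onsets]

        def pack(arr, labels):
            return tuple(TimeSeries(arr[i], fs, lab) for i, lab in enumerate(labels))

        return Recording(
            subject_id=trial.subject_id,
            protocol=trial.protocol,
            environment=trial.environment,
            reps_target=trial.reps,
            arm=trial.arm,
            set_index=trial.set_index,
            semg=TimeSeries(semg, fs, "emg_mv"),
            acc=pack(acc, ("acc_x_g", "acc_y_g", "acc_z_g")),
            gyr=pack(gyr, ("gyr_x_dps", "gyr_y_dps", "gyr_z_dps")),
            mvc_reference_mv=prof.mvc_amplitude_mv,
            annotations=annotations,
        )

    def manifest(self) -> dict:
        """Index of trials and ground-truth onsets (for the on-disk cohort)."""
        cfg = self.config
        n_rest = int(round(cfg.rest_duration_s * cfg.sampling_rate_hz))
        n_con = int(round(cfg.contraction_duration_s * cfg.sampling_rate_hz))
        entries = []
        for t in self.trials:
            slot = n_con // t.reps
            entries.append(
                {
                    "subject_id": t.subject_id,
                    "protocol": t.protocol,
                    "environment": t.environment,
                    "reps": t.reps,
                    "set_index": t.set_index,
                    "arm": t.arm,
                    "true_onsets": [n_rest + r * slot for r in range(t.reps)],
                }
            )
        return {
            "seed": cfg.seed,
            "n_subjects": len(self.subjects),
            "sampling_rate_hz": cfg.sampling_rate_hz,
            "rest_samples": n_rest,
            "trials": entries,
        }


def generate_cohort(n_subjects: int, config: GeneratorConfig | None = None) -> Cohort:
    """Build a lazy cohort: one Recording per subject × protocol × environment
    × rep-count × set."""
    return Cohort(n_subjects, config or GeneratorConfig())
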