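"""Pipeline configuration: per-stage sections, YAML loading, provenance."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import GeneratorConfig

__all__ = [
    "PreprocessingConfig",
    "SegmentationConfig",
    "FeaturesConfig",
    "StatsConfig",
    "ClusteringConfig",
    "PipelineConfig",
]


@dataclass
class PreprocessingConfig:
    semg_band_hz: tuple[float, float] = (20.0, 450.0)
    acc_band_hz: tuple[float, float] = (0.3, 15.0)
    filter_order: int = 4
    zero_phase: bool = True
    envelope_window_ms: float = 100.0
    envelope_hop_ms: float = 10.0
    mvc_window_ms: float = 500.0
    # gravity removed by subtracting the rest-stage per-axis mean; the
    # accelerometer bandpass is available for recordings without a rest stage
    gravity_removal: str = "baseline_mean"  # baseline_mean | bandpass


@dataclass
class SegmentationConfig:
    k_sd: float = 3.0
    min_gap_ms: float = 250.0
    min_duration_ms: float = 100.0
    mode: str = "between_onsets"


@dataclass
class FeaturesConfig:
    welch_window_ms: float = 256.0
    welch_overlap: float = 0.5
    band_hz: tuple[float, float] = (20.0, 450.0)
    imu_statistic: str = "mean"


@dataclass
class StatsConfig:
    equal_var: bool = False
    icc_form: str = "C,1"


@dataclass
class ClusteringConfig:
    k: int = 6
    n_restarts: int = 10
    environment: str = "land"  # cluster within one environment at a time
    feature_set: str = "combined"  # combined | imu_only


@dataclass
class PipelineConfig:
    synthetic: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    features: FeaturesConfig = field(default_factory=FeaturesConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config file; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sections = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(raw) - set(sections)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, value in raw.items():
            f = sections[name]
            if dataclasses.is_dataclass(f.type) or name in (
                "synthetic", "preprocessing", "segmentation", "features", "stats", "clustering",
            ):
                section_cls = f.default_factory  # type: ignore[misc]
                valid = {sf.name for sf in dataclasses.fields(section_cls)}
                bad = set(value) - valid
                if bad:
                    raise ValueError(f"unknown keys in section {name!r}: {sorted(bad)}")
                for key in ("semg_band_hz", "acc_band_hz", "band_hz", "reps_options"):
                    if key in value and isinstance(value[key], list):
                        value[key] = tuple(value[key])
                kwargs[name] = section_cls(**value)
            else:
                kwargs[name] = value
        cfg = cls(**kwargs)
        if "seed" in raw:
            cfg.synthetic.seed = int(raw["seed"])
        return cfg

    def to_dict(self) -> dict:
        def jsonable(obj):
            if isinstance(obj, dict):
                return {
                    (":".join(map(str, k)) if isinstance(k, tuple) else str(k)
                     if not isinstance(k, (str, int, float, bool)) else k): jsonable(v)
                    for k, v in obj.items()
                }
            if isinstance(obj, (list, tuple)):
                return [jsonable(v) for v in obj]
            return obj

        return jsonable(dataclasses.asdict(self))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
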