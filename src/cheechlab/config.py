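"""Hierarchical run configuration with YAML round-trip.

Every defaulted value matches the study protocol where one is stated
(48 kHz stimuli, 18.2 ms / 48 ms chirp spacing, 75 switches over 450 s,
35 ms crossfade, 0.1 Hz / 0.5–40 Hz filter contracts, ±300 µV and 6/2 SD
rejection, 110–160 ms N1 window at Fz); simulation sizes default to a
desk-scale demonstration cohort and are meant to be raised for serious
runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class StimulusConfig:
    rate_hz: float = 48_000.0
    f0_male_hz: float = 128.0
    f0_female_hz: float = 180.0
    story_duration_s: float = 30.0
    min_chirp_isi_s: float = 0.0182
    first_chirp_gap_s: float = 0.048
    chirp_to_speech_ratio: float = 1.0


@dataclass
class TaskConfig:
    n_switches: int = 75
    block_duration_s: float = 450.0
    lag_classes_s: tuple = (0.125, 0.25, 0.5, 1.0, 2.0)
    per_lag_class: int = 5
    crossfade_s: float = 0.035
    hit_window_s: float = 2.0


@dataclass
class ErpConfig:
    simulation_rate_hz: float = 2048.0
    target_rate_hz: float = 512.0
    n1_window_s: tuple = (0.110, 0.160)
    electrode: str = "Fz"
    voltage_threshold_uv: float = 300.0
    single_channel_z: float = 6.0
    across_channel_z: float = 2.0
    background_rms_uv: float = 1.0
    epochs_per_condition: int = 60
    epoch_spacing_s: float = 0.7


@dataclass
class CohortConfig:
    n_participants: int = 24
    beta_tmt_as_printed: bool = False
    residual_sd: float | None = None  # None → √(1 − βᵀRβ)


@dataclass
class PipelineConfig:
    seed: int = 0
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    task: TaskConfig = field(default_factory=TaskConfig)
    erp: ErpConfig = field(default_factory=ErpConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        sections = {
            "stimulus": StimulusConfig,
            "task": TaskConfig,
            "erp": ErpConfig,
            "cohort": CohortConfig,
        }
        for key, klass in sections.items():
            if key in kwargs and isinstance(kwargs[key], dict):
                known = {f.name for f in dataclasses.fields(klass)}
                unknown = set(kwargs[key]) - known
                if unknown:
                    raise ValueError(f"unknown keys in config section {key!r}: {sorted(unknown)}")
                kwargs[key] = klass(**kwargs[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(json.loads(json.dumps(self.to_dict(), default=list)))
        )
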