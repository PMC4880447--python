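"""Structured pipeline configuration.

A YAML document with one section per pipeline stage; unknown keys are
rejected so typos fail loudly. Every default equals the corresponding
module-level constant or documented decision.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class SimulateConfig:
    duration_s: float = 360.0
    n_recordings: int = 5
    protocol: str = "shift"          # constant | shift | ramp
    shift_time_s: float = 180.0
    seed: int = 0


@dataclass
class ExtractConfig:
    threshold: float = 0.5
    scale_mm_per_px: float = 0.0129
    midline_smoothing_mm: float = 0.12
    frame_rate: float = 10.0


@dataclass
class DecomposeConfig:
    basis: str = "fit"               # "fit" or path to a saved basis file
    min_fit_frames: int = 1000


@dataclass
class LocomotionConfig:
    rate_bin_s: float = 10.0
    displacement_bin_s: float = 30.0

    def validate(self) -> None:
        if self.rate_bin_s <= 0 or self.displacement_bin_s <= 0:
            raise ValueError("bin widths must be positive")


@dataclass
class NavigationConfig:
    arena_length_mm: float = 33.0
    arena_width_mm: float = 15.0
    o2_low: float = 4.0
    o2_high: float = 21.0
    optimum: float = 16.0
    zero_crossing_o2: float = 13.8
    bearing_bin_deg: float = 20.0
    apply_restriction: bool = True


@dataclass
class NeuroConfig:
    reference_drop_fraction: float = 0.3
    ratio_mad_limit: float = 5.0
    eta_window_s: float = 8.0
    min_pausing_s: float = 60.0


@dataclass
class ReportConfig:
    profile_bin_s: float = 1.0
    relation_bin_rad: float = 0.1


@dataclass
class PipelineConfig:
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    extract: ExtractConfig = field(default_factory=ExtractConfig)
    decompose: DecomposeConfig = field(default_factory=DecomposeConfig)
    locomotion: LocomotionConfig = field(default_factory=LocomotionConfig)
    navigation: NavigationConfig = field(default_factory=NavigationConfig)
    neuro: NeuroConfig = field(default_factory=NeuroConfig)
    report: ReportConfig = field(default_factory=ReportConfig)

    def validate(self) -> None:
        self.locomotion.validate()
        if self.report.profile_bin_s <= 0 or self.report.relation_bin_rad <= 0:
            raise ValueError("bin widths must be positive")
        if self.simulate.duration_s < 10:
            raise ValueError("simulate.duration_s must be >= 10")

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Stable short hash identifying this configuration."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        sections = {f.name: f for f in fields(cls)}
        unknown = set(data) - set(sections)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        for name, f in sections.items():
            sec_cls = f.default_factory  # type: ignore[union-attr]
            sec_data = data.get(name, {}) or {}
            allowed = {sf.name for sf in fields(sec_cls)}
            bad = set(sec_data) - allowed
            if bad:
                raise ValueError(f"unknown keys in section '{name}': {sorted(bad)}")
            kwargs[name] = sec_cls(**sec_data)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg
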