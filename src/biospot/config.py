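"""Run configuration: every pipeline parameter in one serializable object.

The config round-trips losslessly through YAML; unknown keys are
rejected by name so typos never silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

import yaml

from biospot.correlation import CorrelationConfig
from biospot.errors import ValidationError


@dataclass
class LayoutConfig:
    n_rows: int = 20
    n_cols: int = 10
    pitch_px: float = 16.0
    spot_radius_px: float = 4.0
    block_rows: int = 10
    block_cols: int = 10


@dataclass
class ScheduleConfig:
    t0_min: float = 1.0
    frequency_hz: float = 1.0
    n_fractions: int = 200


@dataclass
class ImagingConfig:
    invert: bool = False
    measure_radius_factor: float = 0.8   # fraction of spot_radius
    halo_weight: float = 1.0
    halo_search_factor: float = 2.0
    k_mad: float = 3.0
    min_contrast: float = 0.05


@dataclass
class ChromatogramConfig:
    sigma_fractions: float = 1.0
    min_prominence: float = 0.5
    min_width_fractions: int = 2


@dataclass
class FeatureConfig:
    ppm_tol: float = 10.0
    min_trace_length: int = 5
    gap_scans: int = 1
    min_intensity: float = 0.0
    min_prominence_rel: float = 0.1
    smooth_sigma: float = 1.0


@dataclass
class CorrelationSection:
    rt_bias_s: float = 0.0
    rt_window_s: float = 10.0
    r_threshold: float = 0.8
    min_overlap_points: int = 5
    mz_tol_ms2: float = 0.01

    def to_correlation_config(self) -> CorrelationConfig:
        return CorrelationConfig(**asdict(self))


_SECTIONS = {
    "layout": LayoutConfig,
    "schedule": ScheduleConfig,
    "imaging": ImagingConfig,
    "chromatogram": ChromatogramConfig,
    "features": FeatureConfig,
    "correlation": CorrelationSection,
}


@dataclass
class RunConfig:
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    chromatogram: ChromatogramConfig = field(default_factory=ChromatogramConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    correlation: CorrelationSection = field(default_factory=CorrelationSection)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ValidationError("config root must be a mapping")
        unknown = set(data) - set(_SECTIONS)
        if unknown:
            raise ValidationError(
                f"unknown config section(s): {', '.join(sorted(unknown))}")
        kwargs = {}
        for name, section_cls in _SECTIONS.items():
            section = data.get(name, {})
            if not isinstance(section, dict):
                raise ValidationError(f"config section '{name}' must be a mapping")
            valid = {f.name for f in fields(section_cls)}
            bad = set(section) - valid
            if bad:
                raise ValidationError(
                    f"unknown key(s) in config section '{name}': "
                    f"{', '.join(sorted(bad))}")
            kwargs[name] = section_cls(**section)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})
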