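"""Pipeline configuration: defaults, strict YAML parsing, echoing.

Every tunable of every stage lives here so a run is fully described by one
resolved mapping. Parsing is strict — unknown keys are an error, not a
warning — because a silently ignored typo in a config would change results
without a trace.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = [
    "PreprocessConfig",
    "WtConfig",
    "RoughConfig",
    "RefineConfig",
    "EvalConfig",
    "PipelineConfig",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised for unknown keys or malformed configuration files."""


@dataclass
class PreprocessConfig:
    wavelet: str = "db4"
    level: int = 2
    threshold_scale: float = 3.0
    remove_pectoral: bool = True
    normalize_first: bool = True  # normalize -> smooth; False reverses the order
    external_mask: str | None = None  # PNG path, nonzero = breast
    # skin-line band excluded from analysis: wavelet denoising rings at the
    # breast/background step and the overshoot reads as bright structure
    edge_margin: int = 4


@dataclass
class WtConfig:
    wavelet: str = "db20"
    level: int = 3
    noise_factor: float = 3.0
    backend: str = "daubechies"  # or gaussian_derivative


@dataclass
class RoughConfig:
    # areas are quoted at 1024x1024 and scaled by actual image area
    min_area: float = 600.0
    max_area: float = 120_000.0
    max_aspect: float = 2.5
    connectivity: int = 8
    axis_aligned_rect: bool = False


@dataclass
class RefineConfig:
    contrast_cutoff: float = 25.0
    tolerance: float = 25.0
    fixed_mean: bool = False
    max_pixels_factor: float = 4.0  # x scaled max_area caps region growth
    sigma1: float = 1.0
    sigma2: float = 1.0
    omega_len: float = 5e-4 * 255.0**2
    w_area: float = 0.0
    local_radius: int = 15
    epsilon: float = 1.5
    dt: float = 0.45
    max_iter: int = 500
    reinit_every: int = 20
    tol: float = 0.5


@dataclass
class EvalConfig:
    rule: str = "centroid_in_circle"
    overlap_fraction: float = 0.3


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    wt: WtConfig = field(default_factory=WtConfig)
    rough: RoughConfig = field(default_factory=RoughConfig)
    refine: RefineConfig = field(default_factory=RefineConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    @classmethod
    def from_mapping(cls, data: dict | None) -> "PipelineConfig":
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError("configuration root must be a mapping")
        cfg = cls()
        sections = {f.name: getattr(cfg, f.name) for f in fields(cfg)}
        for section_name, values in data.items():
            if section_name not in sections:
                raise ConfigError(f"unknown config section {section_name!r}")
            section = sections[section_name]
            if values is None:
                continue
            if not isinstance(values, dict):
                raise ConfigError(f"section {section_name!r} must be a mapping")
            known = {f.name for f in fields(section)}
            for key, value in values.items():
                if key not in known:
                    raise ConfigError(f"unknown key {section_name}.{key}")
                setattr(section, key, value)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
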