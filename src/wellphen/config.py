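"""Run configuration: YAML parsing, defaults, strict key validation."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class FlatfieldConfig:
    sigma_px: float | None = None  # None -> image width / 8
    mode: str = "subtract"  # subtract | divide


@dataclass
class WellConfig:
    major_um: float = 250.0
    minor_um: float = 150.0
    tolerance_frac: float = 0.3
    rim_px: float = 3.0
    max_clip_frac: float = 0.4


@dataclass
class SegmentConfig:
    edge_threshold: float | str = "auto"
    dilate_len_px: int = 3
    erode_iters: int = 2


@dataclass
class ThresholdsConfig:
    nGV_max: float = 0.685
    nSD_GV_min: float = 0.065
    RGVSD_max: float = 9.712
    combine: str = "majority"


@dataclass
class RunConfig:
    input_dir: str | None = None
    output_dir: str | None = None
    sample_sheet: str | None = None
    pixel_size_um: float = 2.0
    flatfield: FlatfieldConfig = field(default_factory=FlatfieldConfig)
    well: WellConfig = field(default_factory=WellConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    thresholds: ThresholdsConfig = field(default_factory=ThresholdsConfig)
    unit: str = "cluster"  # ROC unit: cluster | sample
    save_masks: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "flatfield": FlatfieldConfig,
    "well": WellConfig,
    "segment": SegmentConfig,
    "thresholds": ThresholdsConfig,
}

# accepted python types per (possibly-optional) field
_TYPES = {
    float: (int, float),
    int: (int,),
    str: (str,),
    bool: (bool,),
}


def _check_type(key_path: str, value, default):
    """Coerce/validate a scalar against the type of its default value."""
    if default is None or value is None:
        return value
    if isinstance(default, bool):
        if not isinstance(value, bool):
            raise ConfigError(f"config key {key_path}: expected bool, got {value!r}")
        return value
    if isinstance(default, (int, float)) and not isinstance(default, bool):
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"config key {key_path}: expected number, got {value!r}")
        return type(default)(value)
    if isinstance(default, str):
        # edge_threshold admits "auto" or a number
        if key_path == "segment.edge_threshold" and isinstance(value, (int, float)):
            return float(value)
        if not isinstance(value, str):
            raise ConfigError(f"config key {key_path}: expected string, got {value!r}")
        return value
    return value


def validate_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Parse a YAML config file, inject defaults, and reject unknown keys.

    Either ``path`` or a pre-parsed ``data`` mapping may be given; an empty
    file (or None) yields the full default configuration.
    """
    if data is None:
        if path is None:
            data = {}
        else:
            path = Path(path)
            if not path.exists():
                raise ConfigError(f"config file not found: {path}")
            data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")

    cfg = RunConfig()
    for key, value in data.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigError(f"config key {key}: expected a mapping")
            section = getattr(cfg, key)
            for sub, subval in value.items():
                if not hasattr(section, sub):
                    raise ConfigError(f"unknown config key: {key}.{sub}")
                default = getattr(_SECTIONS[key](), sub)
                setattr(section, sub, _check_type(f"{key}.{sub}", subval, default))
        elif hasattr(cfg, key) and key not in ("flatfield", "well", "segment", "thresholds"):
            default = getattr(RunConfig(), key)
            setattr(cfg, key, _check_type(key, value, default))
        else:
            raise ConfigError(f"unknown config key: {key}")

    for attr in ("input_dir", "sample_sheet"):
        p = getattr(cfg, attr)
        if p is not None and not Path(p).exists():
            raise ConfigError(f"config key {attr}: path does not exist: {p}")
    return cfg
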