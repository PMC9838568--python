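"""Pipeline configuration: one strict, YAML-round-trippable object.

Unknown keys are rejected so a typo in a config file fails loudly instead
of silently running with defaults.
"""

from __future__ import annotations

import dataclasses
import types
import typing
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import InputError
from .fusion import (
    DEFAULT_ASSOCIATION_TOLERANCE_S,
    DEFAULT_FOOTPRINT_RADIUS_PX,
    GuidanceThresholds,
)
from .geometry import CalibrationModel
from .mosaic import DEFAULT_BIN_WIDTH_MM, DEFAULT_MIN_PEAK
from .scoring import DEFAULT_UM_PER_PX, MorphometryReference, QCParams
from .tracking import ColorGate

__all__ = ["PipelineConfig", "ScorerConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class ScorerConfig:
    kind: str = "morphometry"  # "morphometry" | "constant"
    constant_value: float = 0.5
    weights: tuple[float, float, float, float] = (0.0, 1.0, 1.0, 1.0)
    reference: MorphometryReference = field(default_factory=MorphometryReference)
    um_per_px: float = DEFAULT_UM_PER_PX
    min_nucleus_area: float = 12.0
    max_nucleus_area: float = 2000.0
    expected_radius_px: float = 4.0

    def __post_init__(self) -> None:
        if self.kind not in ("morphometry", "constant"):
            raise InputError(f"unknown scorer kind {self.kind!r}")


@dataclass(frozen=True)
class PipelineConfig:
    calibration: CalibrationModel = field(default_factory=CalibrationModel)
    gate: ColorGate = field(default_factory=ColorGate)
    qc: QCParams = field(default_factory=QCParams)
    scorer: ScorerConfig = field(default_factory=ScorerConfig)
    association_tolerance_s: float = DEFAULT_ASSOCIATION_TOLERANCE_S
    footprint_radius_px: int = DEFAULT_FOOTPRINT_RADIUS_PX
    thresholds: GuidanceThresholds | None = None
    norm_stat: str = "mean"
    green_epsilon: float = 1.0
    smooth_window: int = 5
    max_gap: int = 5
    mosaic_min_peak: float = DEFAULT_MIN_PEAK
    profile_bin_width_mm: float = DEFAULT_BIN_WIDTH_MM
    homography_path: str | None = None
    downsample_factor: int = 1
    enable_mosaic: bool = False
    enable_profile: bool = False

    def __post_init__(self) -> None:
        if self.norm_stat not in ("mean", "median"):
            raise InputError("norm_stat must be 'mean' or 'median'")
        if self.association_tolerance_s <= 0:
            raise InputError("association_tolerance_s must be positive")
        if self.footprint_radius_px < 0:
            raise InputError("footprint_radius_px must be >= 0")
        if self.downsample_factor < 1:
            raise InputError("downsample_factor must be >= 1")


def _from_dict(cls, data):
    """Build a (possibly nested) dataclass from a dict, rejecting unknown keys."""
    if data is None:
        return None
    if not dataclasses.is_dataclass(cls):
        raise TypeError(f"{cls} is not a dataclass")
    if not isinstance(data, dict):
        raise InputError(f"expected a mapping for {cls.__name__}, got {type(data).__name__}")
    hints = typing.get_type_hints(cls)
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise InputError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        ftype = hints[f.name]
        origin = typing.get_origin(ftype)
        args = typing.get_args(ftype)
        if origin in (typing.Union, types.UnionType) and type(None) in args:  # Optional[...]
            ftype = next(a for a in args if a is not type(None))
            origin = typing.get_origin(ftype)
        if value is None:
            kwargs[f.name] = None
        elif dataclasses.is_dataclass(ftype):
            kwargs[f.name] = _from_dict(ftype, value)
        elif origin is tuple:
            kwargs[f.name] = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        else:
            kwargs[f.name] = value
    return cls(**kwargs)


def _to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_dict(v) for v in obj]
    return obj


def load_config(path: str | Path | None) -> PipelineConfig:
    """Read a YAML config; ``None`` yields the defaults."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _from_dict(PipelineConfig, data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(config), sort_keys=False))
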