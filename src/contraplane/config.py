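"""Validated hierarchical configuration for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

__all__ = ["LocalizationConfig", "PlaneConfig", "MaskConfig", "ViewConfig", "PipelineConfig"]


def _check_range(name, value, lo=None, hi=None):
    if lo is not None and value < lo:
        raise ValueError(f"{name}={value} below minimum {lo}")
    if hi is not None and value > hi:
        raise ValueError(f"{name}={value} above maximum {hi}")


@dataclass(frozen=True)
class LocalizationConfig:
    patch_size: int = 64
    stride: int = 32
    weight_floor: float = 0.05
    merge_distance_mm: float = 40.0

    def __post_init__(self):
        _check_range("localization.patch_size", self.patch_size, 8)
        _check_range("localization.stride", self.stride, 1)
        _check_range("localization.weight_floor", self.weight_floor, 0.0, 1.0)


@dataclass(frozen=True)
class PlaneConfig:
    crop_size_unilateral: int = 128
    crop_size_bilateral: int = 80
    min_voxels: int = 50
    intersection_mode: str = "centroid-mean"

    def __post_init__(self):
        _check_range("planes.crop_size_unilateral", self.crop_size_unilateral, 16)
        _check_range("planes.crop_size_bilateral", self.crop_size_bilateral, 16)
        if self.intersection_mode not in ("centroid-mean", "pooled"):
            raise ValueError("planes.intersection_mode must be 'centroid-mean' or 'pooled'")


@dataclass(frozen=True)
class MaskConfig:
    radius_mm: float = 25.0
    height_mm: float = 2.0
    sphere_radius_mm: float = 5.0

    def __post_init__(self):
        _check_range("masks.radius_mm", self.radius_mm, 1.0)
        _check_range("masks.height_mm", self.height_mm, 0.1)


@dataclass(frozen=True)
class ViewConfig:
    extent_mm: float = 60.0
    pixel_mm: float = 0.5
    display_side: str = "right"

    def __post_init__(self):
        _check_range("view.extent_mm", self.extent_mm, 1.0)
        _check_range("view.pixel_mm", self.pixel_mm, 0.01)
        if self.display_side not in ("left", "right"):
            raise ValueError("view.display_side must be 'left' or 'right'")


@dataclass(frozen=True)
class PipelineConfig:
    localization: LocalizationConfig = field(default_factory=LocalizationConfig)
    planes: PlaneConfig = field(default_factory=PlaneConfig)
    masks: MaskConfig = field(default_factory=MaskConfig)
    view: ViewConfig = field(default_factory=ViewConfig)
    seed: int = 0

    _SECTIONS = {
        "localization": LocalizationConfig,
        "planes": PlaneConfig,
        "masks": MaskConfig,
        "view": ViewConfig,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = {}
        for key, value in (data or {}).items():
            if key == "seed":
                kwargs["seed"] = int(value)
            elif key in cls._SECTIONS:
                section_cls = cls._SECTIONS[key]
                known = {f.name for f in fields(section_cls)}
                unknown = set(value) - known
                if unknown:
                    raise ValueError(f"unknown keys in section '{key}': {sorted(unknown)}")
                kwargs[key] = section_cls(**value)
            else:
                raise ValueError(f"unknown configuration section '{key}'")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return asdict(self)
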