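"""Run configuration: parameter blocks for every pipeline stage, YAML round-trip."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigurationError(ValueError):
    """Raised when a parameter block violates its contract."""


@dataclass
class DetectionParams:
    """Microwell detection parameters.

    Radius range targets the outer rim radius; the gradient threshold is
    applied to the un-normalised Roberts magnitude before circle search.
    """

    r_min: float = 80.0
    r_max: float = 86.0
    sensitivity: float = 0.975
    edge_threshold: float = 0.030
    gradient_threshold: float = 0.015
    pitch_px: float = 225.0
    strength_fraction: float = 0.5

    def validate(self) -> None:
        if self.r_min > self.r_max:
            raise ConfigurationError(f"r_min ({self.r_min}) > r_max ({self.r_max})")
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ConfigurationError("sensitivity must be in [0, 1]")
        if self.pitch_px <= 0:
            raise ConfigurationError("pitch_px must be positive")
        if not 0.0 < self.strength_fraction <= 1.0:
            raise ConfigurationError("strength_fraction must be in (0, 1]")
        if self.gradient_threshold < 0:
            raise ConfigurationError("gradient_threshold must be >= 0")


@dataclass
class SegmentationParams:
    inner_radius_px: float = 75.0
    gradient_threshold: float = 0.020
    otsu_bins: int = 256
    polarity: str = "dark"  # dark: foreground below the Otsu threshold
    small_keep: int = 25
    hole_fill: int = 150
    disk_r: int = 2
    # minimum Otsu class separation for the adaptive threshold to be trusted;
    # below it the intensity branch is treated as degenerate (cell-free well)
    min_contrast: float = 0.04

    def validate(self) -> None:
        if self.inner_radius_px <= 0:
            raise ConfigurationError("inner_radius_px must be positive")
        if self.polarity not in ("dark", "bright"):
            raise ConfigurationError("polarity must be 'dark' or 'bright'")
        if self.otsu_bins < 2:
            raise ConfigurationError("otsu_bins must be >= 2")


@dataclass
class TrackingParams:
    # inner radius + half the inter-well gap: 75 + 37 px at the default scale
    max_shift_px: float = 112.0

    def validate(self) -> None:
        if self.max_shift_px <= 0:
            raise ConfigurationError("max_shift_px must be positive")


@dataclass
class RunConfig:
    input_dir: str = "."
    pattern: str = "*.tif"
    output_dir: str = "out"
    frame_interval_min: float = 5.0
    pixel_size_um: float = 1.333
    seed: int = 0
    log_level: str = "INFO"
    save_masks: bool = False
    save_overlays: bool = False
    detection: DetectionParams = field(default_factory=DetectionParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)

    def validate(self) -> None:
        self.detection.validate()
        self.segmentation.validate()
        self.tracking.validate()
        if self.frame_interval_min <= 0:
            raise ConfigurationError("frame_interval_min must be positive")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        kwargs: dict[str, Any] = {}
        for block, typ in (
            ("detection", DetectionParams),
            ("segmentation", SegmentationParams),
            ("tracking", TrackingParams),
        ):
            if block in d:
                sub = d.pop(block)
                kwargs[block] = typ(**sub) if isinstance(sub, dict) else sub
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(d)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
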