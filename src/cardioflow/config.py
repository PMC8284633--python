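"""Pipeline configuration: a single validated document (JSON or YAML)."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml


@dataclass
class GatingOptions:
    prominence_threshold: float = 0.1
    canonical_phase: bool = False

    def validate(self) -> None:
        if not (0 < self.prominence_threshold < 1):
            raise ValueError("prominence threshold must lie in (0, 1)")


@dataclass
class RegistrationOptions:
    iterations: tuple[int, ...] = (100, 50, 25)
    smoothing_sigma: float = 1.5
    temporal_window: int = 7
    mask_radius_um: float = 30.0
    intensity_threshold: Optional[float] = None

    def validate(self) -> None:
        if not self.iterations or any(i < 1 for i in self.iterations):
            raise ValueError("iteration counts must be positive")
        if self.smoothing_sigma <= 0:
            raise ValueError("smoothing sigma must be positive")
        if self.temporal_window % 2 == 0 or self.temporal_window < 1:
            raise ValueError("temporal window must be odd and positive")
        if self.mask_radius_um <= 0:
            raise ValueError("mask radius must be positive")


@dataclass
class TrackingOptions:
    blur_sigma: float = 1.0
    intensity_threshold: Optional[float] = None
    min_separation_um: float = 6.0
    max_displacement_um: Optional[float] = None
    max_gap: int = 1
    min_duration: int = 5

    def validate(self) -> None:
        if self.blur_sigma < 0:
            raise ValueError("blur sigma must be nonnegative")
        if self.min_separation_um <= 0:
            raise ValueError("min separation must be positive")
        if self.max_gap < 0 or self.min_duration < 1:
            raise ValueError("max_gap must be >= 0 and min_duration >= 1")


@dataclass
class FlowgeomOptions:
    center_um: Optional[tuple[float, float, float]] = None
    av_end: str = "min"
    av_point_um: Optional[tuple[float, float, float]] = None
    n_segments: int = 4
    reversal_threshold_um_s: float = 1000.0
    systole_window: Optional[tuple[int, int]] = None
    diastole_window: Optional[tuple[int, int]] = None

    def validate(self) -> None:
        if self.n_segments < 2 or self.n_segments % 2:
            raise ValueError("n_segments must be even and >= 2")
        if self.av_end not in ("min", "max"):
            raise ValueError("av_end must be 'min' or 'max'")
        if self.reversal_threshold_um_s < 0:
            raise ValueError("reversal threshold must be nonnegative")


@dataclass
class PipelineConfig:
    """All pipeline parameters; numeric options are validated up front."""

    output_dir: str = "cardioflow_out"
    scan_dir: Optional[str] = None          # slice scan input (else phantom)
    particle_volume: Optional[str] = None   # particle 4-D TIFF input (else phantom)
    frame_rate_hz: float = 200.0
    seed: int = 0
    gating: GatingOptions = field(default_factory=GatingOptions)
    registration: RegistrationOptions = field(default_factory=RegistrationOptions)
    tracking: TrackingOptions = field(default_factory=TrackingOptions)
    flowgeom: FlowgeomOptions = field(default_factory=FlowgeomOptions)

    def validate(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be positive")
        self.gating.validate()
        self.registration.validate()
        self.tracking.validate()
        self.flowgeom.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        sub = {
            "gating": GatingOptions,
            "registration": RegistrationOptions,
            "tracking": TrackingOptions,
            "flowgeom": FlowgeomOptions,
        }
        kwargs = {}
        for key, val in doc.items():
            if key in sub:
                opts = sub[key](**val)
                kwargs[key] = opts
            else:
                kwargs[key] = val
        cfg = cls(**kwargs)
        if isinstance(cfg.registration.iterations, list):
            cfg.registration.iterations = tuple(cfg.registration.iterations)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            if path.suffix in (".yaml", ".yml"):
                doc = yaml.safe_load(fh)
            else:
                doc = json.load(fh)
        return cls.from_dict(doc or {})

    def to_file(self, path: Union[str, Path]) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in (".yaml", ".yml"):
                yaml.safe_dump(self.to_dict(), fh)
            else:
                json.dump(self.to_dict(), fh, indent=1)
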