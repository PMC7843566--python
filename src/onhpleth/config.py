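"""Run configuration with documented defaults.

Defaults follow the acquisition and processing conventions of the method:
25 frames/s video, 5-pixel circular vessel dilation, 30-70% rise
steepness, 2-7 selected pulses per sequence.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    fps: float = 25.0
    trend_window_s: float | None = None  # None: adaptive, two detected beat periods
    steepness_variant: str = "rise_30_70"
    dilation_diameter_px: int = 5
    selection_mode: str = "auto"  # "manual" requires a label file
    duration_tolerance: float = 0.25
    amplitude_tolerance: float = 0.50
    min_pulses: int = 2
    max_pulses: int = 7
    averaging_mode: str = "resample"
    sequence_policy: str = "most_pulses"  # which of a subject's sequences to keep
    bonferroni_family: str = "per_parameter"  # or "global"
    max_rotation_deg: float = 3.0
    confidence_threshold: float = 0.3
    roi_min_pixels: int = 500
    onh_threshold_quantile: float = 0.90
    allow_auto_onh: bool = True
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.selection_mode not in ("auto", "manual"):
            raise ValueError("selection_mode must be 'auto' or 'manual'")
        if self.bonferroni_family not in ("per_parameter", "global"):
            raise ValueError("bonferroni_family must be 'per_parameter' or 'global'")
        if self.min_pulses < 1 or self.max_pulses < self.min_pulses:
            raise ValueError("need 1 <= min_pulses <= max_pulses")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
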