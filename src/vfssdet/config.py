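"""Structured pipeline configuration.

A single flat config is the source of truth for every stage threshold and
size; CLI flags override it, and each run writes its resolved config beside
its outputs.  The stage defaults (fth, vth, window/stride, scoreth, frameth,
lambda, IOU threshold, FPS, the 10-frame review pad) are the operating
points of the published cascade; the network/synthetic sizes default to desk
scale so an end-to-end run finishes in minutes on one CPU.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    # candidate generation
    fth: float = 0.4
    vth: float = 2.5
    max_candidates: int = 5
    center_fraction: float = 0.5
    radius: int = 4
    # detection
    window: int = 20
    stride: int = 5
    scoreth: float = 0.5
    frameth: int = 5
    lam: float = 0.001
    smooth_width: int = 5
    pad: int = 10
    # evaluation
    iou_th: float = 0.3
    fps: float = 15.0
    # network
    variant: str = "proposed"
    stream: str = "rgb"
    schedule: str = "toy"          # "toy" | "default"
    input_size: int = 48
    # training
    iterations: int = 300
    warmup: int = 50
    lr: float = 0.1
    batch_size: int = 6
    seed: int = 0
    # synthetic data
    n_train_videos: int = 20
    n_test_videos: int = 5
    duration_frames: int = 72
    frame_size: int = 48
    n_events_max: int = 2
    event_duration_max: int = 12
    event_speed_max: float = 6.5
    hard_negative_fraction: float = 0.5
    # flow solver
    num_warp: int = 5
    num_iter: int = 10

    def __post_init__(self):
        if self.smooth_width % 2 == 0 or self.smooth_width < 1:
            raise ConfigError("smooth_width must be odd and >= 1")
        if self.schedule not in ("toy", "default"):
            raise ConfigError(f"schedule must be toy|default, got {self.schedule}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True,
                              default_flow_style=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def load_config(path: str | None, **overrides) -> PipelineConfig:
    """Read a YAML config (or defaults) and apply non-None overrides."""
    if path:
        with open(path) as fh:
            cfg = PipelineConfig.from_yaml(fh.read())
    else:
        cfg = PipelineConfig()
    fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    updates = {k: v for k, v in overrides.items() if v is not None}
    unknown = set(updates) - fields
    if unknown:
        raise ConfigError(f"unknown config overrides: {sorted(unknown)}")
    return dataclasses.replace(cfg, **updates)
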