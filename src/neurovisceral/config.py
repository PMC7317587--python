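"""Pipeline configuration, validated against each stage's preconditions."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .connectivity import BANDS

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # HRV
    fs_interp: float = 4.0
    ar_order: int = 16
    segment_s: float = 50.0
    # coherence
    window_s: float = 2.0
    overlap: float = 0.75
    taper: str = "hann"
    artifact_threshold: float | None = None  # amplitude units; None = no rejection
    bands: tuple = BANDS
    # graph
    length_transform: str = "inverse"
    proportional_threshold: float | None = None
    # stats
    alpha: float = 0.05
    covariates: tuple = ("IQ",)
    # misc
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_interp <= 0 or self.ar_order < 2 or self.segment_s <= 0:
            raise ValueError("invalid HRV options")
        if self.window_s < 2.0 or not 0 <= self.overlap <= 0.95:
            raise ValueError("invalid coherence options")
        if self.length_transform not in ("inverse", "log"):
            raise ValueError("length_transform must be 'inverse' or 'log'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "bands" in raw:
            raw["bands"] = tuple(tuple(b) for b in raw["bands"])
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
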