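"""Run configuration with lossless YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Settings shared by the pipeline stages.

    Precedence when running from the command line is flag > config file >
    these built-in defaults.
    """

    fps: float = 30.0
    lags_s: list[float] = field(default_factory=lambda: [1.0, 2.0, 3.0, 5.0, 7.0, 11.0, 13.0])
    oks_s: float = 1.0
    oks_k: float = 0.001
    oks_variant: str = "paper"
    oks_normalize_by_diagonal: bool = False
    ttest_variant: str = "pooled"
    alpha: float = 0.05
    min_confidence: float = 0.0
    max_gap_frames: int = 5
    duration_s: float = 180.0
    n_per_group: int = 5
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if not self.lags_s:
            raise ValueError("lag grid must be non-empty")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        self.lags_s = [float(l) for l in self.lags_s]

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        payload = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())
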