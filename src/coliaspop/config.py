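"""Run configuration: seeds, window sizes, thresholds; TOML round-trip."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    seed: int = 0
    window_bp: int = 10_000
    coverage_window_bp: int = 600
    snps_per_window: int = 500
    jackknife_blocks: int = 20
    alpha: float = 0.05
    outlier_percentile: float = 95.0
    rnd_lower_quantile: float = 0.05
    afs_percentile: float = 95.0
    min_depth: float = 1.0
    min_covered_fraction: float = 0.5
    min_gq: float = 20.0

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.coverage_window_bp <= 0 or self.snps_per_window <= 0:
            raise ValueError("window sizes must be > 0")
        if self.jackknife_blocks < 3:
            raise ValueError("need >= 3 jackknife blocks")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("outlier_percentile", "afs_percentile"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise ValueError(f"{name} must be in (0, 100)")
        if not 0 < self.rnd_lower_quantile < 1:
            raise ValueError("rnd_lower_quantile must be in (0, 1)")
        if not 0 <= self.min_covered_fraction <= 1:
            raise ValueError("min_covered_fraction must be in [0, 1]")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_toml(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            lines.append(f"{f.name} = {v!r}" if isinstance(v, bool) else f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")
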