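"""Run configuration: a nested key/value YAML file, overridable per CLI flag."""

from __future__ import annotations

import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class Thresholds:
    correlation_alpha: float = 0.05   # p cutoff for PC-profile correlation
    trim_quantile: float = 0.02       # per-array tail trim of Log2Ratios
    filter_quartile: float = 0.25     # low-expression floor on log2 medians
    utilization_quantile: float = 0.75  # "highly expressed" threshold
    qtest_confidence: float = 0.95    # Dixon Q critical-value level

    def __post_init__(self) -> None:
        if not 0 <= self.trim_quantile < 0.5:
            raise ConfigError("trim_quantile must lie in [0, 0.5)")
        if not 0 < self.filter_quartile < 1:
            raise ConfigError("filter_quartile must lie in (0, 1)")
        if not 0 < self.utilization_quantile < 1:
            raise ConfigError("utilization_quantile must lie in (0, 1)")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "germomics-out"
    thresholds: Thresholds = field(default_factory=Thresholds)
    inputs: dict = field(default_factory=dict)   # named input paths
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        known = {"seed", "out_dir", "inputs", "simulation"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(thresholds=thr, **raw)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def log_stage(stage: str, message: str, logfile: str | None = None) -> None:
    """Stage logging: entity counts in/out and thresholds applied."""
    line = f"[germomics:{stage}] {message}"
    print(line, file=sys.stderr)
    if logfile:
        with open(logfile, "a") as fh:
            fh.write(line + "\n")
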