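"""Run configuration: a validated key-value surface shared by the CLI.

A config file (YAML) provides defaults; command-line flags override.
Unknown keys are rejected so that typos never silently fall back to
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    r_max: float = 3.5
    theta_min: float = 140.0
    mode: str = "full"
    min_separation: int = 2
    model_index: int = 1
    threshold: float = 0.5
    band_low: float = 0.4
    site_cutoff: float = 6.0
    frame_start: int = 0
    frame_end: int | None = None
    frame_stride: int = 1
    windows: int = 1
    replicas: list[str] | None = None
    exclude_bonds: list[str] | None = None
    output_dir: str = "."
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self):
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if not (0 < self.theta_min <= 180):
            raise ValueError("theta_min must be in (0, 180]")
        if self.mode not in ("full", "distance_only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")
        if self.model_index < 1:
            raise ValueError("model_index is 1-based")
        if not (0 < self.band_low < self.threshold <= 1):
            raise ValueError("need 0 < band_low < threshold <= 1")
        if self.site_cutoff <= 0:
            raise ValueError("site_cutoff must be positive")
        if self.frame_stride < 1 or self.frame_start < 0 or self.windows < 1:
            raise ValueError("frame range / windows out of range")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


def load_config(path) -> RunConfig:
    """Load and validate a YAML config file; unknown keys are an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
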