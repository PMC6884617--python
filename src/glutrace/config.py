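"""Pipeline configuration: strict plain-text (YAML) schema."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .network import TRACERS
from .presets import PRESETS

__all__ = ["PipelineConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration.

    ``conditions`` and ``tracers`` select the simulated experiments;
    the thresholds drive the untargeted screen; every random stage
    derives its stream from ``seed``.
    """

    conditions: tuple[str, ...] = ("HEP-L", "HDF")
    tracers: tuple[str, ...] = ("U13C15N2-Gln", "U13C-Glc", "5-13C-Gln", "1-13C-Gln")
    n_replicates: int = 7
    mid_noise_cv: float = 0.05
    conc_noise_cv: float = 0.05
    fold_change_threshold: float = 2.0
    fdr_threshold: float = 0.005
    n_features: int = 858
    n_changed_features: int = 101
    seed: int = 0
    output_dir: str = "glutrace-out"

    def __post_init__(self) -> None:
        unknown_cond = set(self.conditions) - set(PRESETS)
        if unknown_cond:
            raise ConfigError(f"unknown conditions: {sorted(unknown_cond)}")
        unknown_tr = set(self.tracers) - set(TRACERS)
        if unknown_tr:
            raise ConfigError(f"unknown tracers: {sorted(unknown_tr)}")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        if self.fold_change_threshold <= 0 or self.fdr_threshold <= 0:
            raise ConfigError("thresholds must be positive")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
    for key in ("conditions", "tracers"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)
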