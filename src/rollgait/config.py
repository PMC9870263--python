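"""Run configuration with YAML loading and schema validation.

Defaults mirror the study protocol: 60 Hz sampling, a 10-second standing
calibration, 20-second analysis windows, cross-correlation alignment
bounded at ±5 s, and α = 0.05 for the timepoint comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .orientation import VALID_CONVENTIONS


@dataclass
class SimConfig:
    """Simulator block of the run configuration."""

    n_participants: int = 20
    duration_s: float = 20.0
    calibration_s: float = 10.0
    noise: bool = True
    max_lag_samples: int = 30
    lag_pad_s: float = 2.0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("sim.n_participants must be >= 1")
        if self.duration_s <= 0:
            raise ConfigError("sim.duration_s must be positive")
        if self.calibration_s <= 0:
            raise ConfigError("sim.calibration_s must be positive")
        if self.max_lag_samples < 0:
            raise ConfigError("sim.max_lag_samples must be non-negative")
        if self.lag_pad_s < 0:
            raise ConfigError("sim.lag_pad_s must be non-negative")


@dataclass
class RunConfig:
    rate_hz: float = 60.0
    euler_convention: str = "ZYX"
    max_lag_s: float = 5.0
    alpha: float = 0.05
    regression_predictor: str = "sensor"      # or "reference"
    alignment_joint: str = "knee"             # "hip", "knee" or "per_joint"
    flip_hip_sign: bool = False
    flip_knee_sign: bool = False
    calibration_window_s: tuple[float, float] | None = None
    pooled: bool = True
    seed: int | None = None
    sim: SimConfig = field(default_factory=SimConfig)

    def validate(self) -> None:
        if self.rate_hz <= 0:
            raise ConfigError("rate_hz must be positive")
        if self.euler_convention not in VALID_CONVENTIONS:
            raise ConfigError(
                f"euler_convention must be one of {VALID_CONVENTIONS}, "
                f"got {self.euler_convention!r}"
            )
        if self.max_lag_s <= 0:
            raise ConfigError("max_lag_s must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.regression_predictor not in ("sensor", "reference"):
            raise ConfigError("regression_predictor must be 'sensor' or 'reference'")
        if self.alignment_joint not in ("hip", "knee", "per_joint"):
            raise ConfigError("alignment_joint must be 'hip', 'knee' or 'per_joint'")
        if self.calibration_window_s is not None:
            lo, hi = self.calibration_window_s
            if not (0 <= lo < hi):
                raise ConfigError("calibration_window_s must be (start_s, end_s)")
        self.sim.validate()


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected with the offending field name so typos in
    config files fail loudly rather than silently using defaults.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config fields {sorted(unknown)}")
    sim_raw = raw.pop("sim", {}) or {}
    sim_known = {f.name for f in fields(SimConfig)}
    sim_unknown = set(sim_raw) - sim_known
    if sim_unknown:
        raise ConfigError(f"{path}: unknown sim fields {sorted(sim_unknown)}")
    if "calibration_window_s" in raw and raw["calibration_window_s"] is not None:
        raw["calibration_window_s"] = tuple(raw["calibration_window_s"])
    config = RunConfig(sim=SimConfig(**sim_raw), **raw)
    config.validate()
    return config
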