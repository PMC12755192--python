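"""Configuration models for a trait-database build.

Everything tunable in the workflow lives here, validated by pydantic and
round-trippable through a YAML file, so a build is fully described by its
config (plus the input tables and a seed for any stochastic step).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

#: resampling intervals, seconds
HOURLY = 3600
DAILY = 86400
WEEKLY = 604800

INTERVAL_NAMES = {HOURLY: "hourly", DAILY: "daily", WEEKLY: "weekly"}

TRAITS = ("displacement", "max_displacement", "range_size",
          "intensity_of_use", "diurnality")

TIMESCALES = ("hourly", "daily", "weekly", "monthly", "annual", "whole_track")


class CleaningParams(BaseModel):
    """Fix-level quality control.

    ``max_speed_ms`` — per movement-mode speed ceiling (m/s); a fix whose
    implied speed to *both* temporal neighbours exceeds the ceiling is
    removed (iterated until stable). Off by default: cleaning beyond
    duplicate removal is study-specific.
    """
    max_speed_ms: dict[str, float] = Field(default_factory=dict)
    drop_duplicate_timestamps: bool = True

    @field_validator("max_speed_ms")
    @classmethod
    def _positive(cls, v):
        for mode, s in v.items():
            if s <= 0:
                raise ValueError(f"max_speed_ms[{mode!r}] must be > 0")
        return v

    def speed_limit(self, movement_mode: str = "unknown") -> Optional[float]:
        if movement_mode in self.max_speed_ms:
            return self.max_speed_ms[movement_mode]
        return self.max_speed_ms.get("default")


class ResampleConfig(BaseModel):
    """Nearest-fix tolerance per interval, seconds.

    Defaults (15 min / 6 h / 1 day) are <= interval/4, bounding the
    displacement bias a loose tolerance would introduce.
    """
    tolerance_s: dict[int, int] = Field(
        default_factory=lambda: {HOURLY: 900, DAILY: 21600, WEEKLY: 86400})

    def tolerance(self, interval: int) -> int:
        try:
            return self.tolerance_s[interval]
        except KeyError:
            return max(1, interval // 4)


class ThresholdConfig(BaseModel):
    """Minimum-data rules.

    ``min_fixes`` — fixes required inside a window before a windowed metric
    is estimated (keys ``"<trait>.<timescale>"``). Only the monthly
    range-size floor (14 daily fixes) is a published rule; the rest are
    package defaults, all configurable.

    ``min_estimates`` — repeated estimates required before an individual
    summary is produced. Daily displacement needs 30 (the "at least 30 days
    of data" rule); diurnality is a single whole-track value so its floor is
    1; everything else defaults to 20.
    """
    min_fixes: dict[str, int] = Field(default_factory=lambda: {
        "max_displacement.daily": 18,
        "max_displacement.weekly": 120,
        "max_displacement.annual": 200,
        "range_size.daily": 18,
        "range_size.weekly": 120,
        "range_size.monthly": 14,
        "range_size.annual": 200,
        "intensity_of_use.daily": 18,
        "intensity_of_use.monthly": 14,
        "diurnality.whole_track": 720,
    })
    min_estimates: dict[str, int] = Field(default_factory=lambda: {
        "displacement.daily": 30,
        "diurnality.whole_track": 1,
    })
    default_min_estimates: int = 20
    min_individuals_species: int = 1

    @model_validator(mode="after")
    def _counts(self):
        for d in (self.min_fixes, self.min_estimates):
            for k, v in d.items():
                if v < 1:
                    raise ValueError(f"threshold {k} must be >= 1")
        if self.min_individuals_species < 1 or self.default_min_estimates < 1:
            raise ValueError("thresholds must be >= 1")
        return self

    def fixes_for(self, trait: str, timescale: str) -> int:
        return self.min_fixes.get(f"{trait}.{timescale}", 1)

    def estimates_for(self, trait: str, timescale: str) -> int:
        return self.min_estimates.get(f"{trait}.{timescale}",
                                      self.default_min_estimates)


class GridSpec(BaseModel):
    """Spatial-diffusion grid: cells of ~``cell_area_km2`` built from
    latitude bands; coordinates are reported as cell centres only."""
    cell_area_km2: float = 100.0

    @field_validator("cell_area_km2")
    @classmethod
    def _allowed(cls, v):
        if v not in (1, 100, 10000):
            raise ValueError("cell_area_km2 must be one of {1, 100, 10000}")
        return float(v)

    @property
    def cell_side_km(self) -> float:
        return self.cell_area_km2 ** 0.5


class TraitsConfig(BaseModel):
    enabled: list[str] = Field(default_factory=lambda: list(TRAITS))
    sun_threshold_deg: float = 0.0
    distance_radius_m: float = 6_371_000.0
    mcp_retain: float = 0.95

    @field_validator("enabled")
    @classmethod
    def _known(cls, v):
        unknown = set(v) - set(TRAITS)
        if unknown:
            raise ValueError(f"unknown traits: {sorted(unknown)}")
        return v

    @field_validator("mcp_retain")
    @classmethod
    def _retain(cls, v):
        if not (0 < v <= 1):
            raise ValueError("mcp_retain must be in (0, 1]")
        return v


class BuildConfig(BaseModel):
    """Everything a `build` run needs besides the input tables."""
    column_map: dict[str, str] = Field(default_factory=dict)
    timezone_policy: str = "utc"  # how naive timestamps are interpreted
    cleaning: CleaningParams = Field(default_factory=CleaningParams)
    resample: ResampleConfig = Field(default_factory=ResampleConfig)
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    grid: GridSpec = Field(default_factory=GridSpec)
    traits: TraitsConfig = Field(default_factory=TraitsConfig)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BuildConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)


class MigrationLeg(BaseModel):
    start_day: float
    length_days: float
    heading_deg: float
    bias_strength: float = 0.9  # wrapped-Cauchy concentration toward heading

    @field_validator("bias_strength")
    @classmethod
    def _rho(cls, v):
        if not (0 <= v < 1):
            raise ValueError("bias_strength must be in [0, 1)")
        return v


class SimulationParams(BaseModel):
    """Ground-truth correlated random walk for one simulated deployment.

    Step lengths are Gamma(k=``step_shape``, theta=``step_scale`` m), scaled
    by ``day_activity_multiplier`` when the step starts in daylight; headings
    accumulate wrapped-Cauchy innovations with concentration
    ``turn_concentration`` (0 = uncorrelated turning).
    """
    n_individuals: int = 1
    interval_s: int = HOURLY
    duration_days: float = 30.0
    step_shape: float = 2.0
    step_scale_m: float = 250.0
    turn_concentration: float = 0.0
    day_activity_multiplier: float = 1.0
    migration: Optional[MigrationLeg] = None
    gap_rate: float = 0.0
    noise_sd_m: float = 0.0
    origin_lon: float = 0.0
    origin_lat: float = 0.0
    start_time: str = "2023-01-01T00:00:00Z"
    species: str = "Simulans exemplaris"
    seed: int = 0

    @model_validator(mode="after")
    def _valid(self):
        if self.step_shape <= 0 or self.step_scale_m <= 0:
            raise ValueError("gamma step parameters must be > 0")
        if not (0 <= self.turn_concentration < 1):
            raise ValueError("turn_concentration must be in [0, 1)")
        if not (0 <= self.gap_rate < 1):
            raise ValueError("gap_rate must be in [0, 1)")
        if self.noise_sd_m < 0:
            raise ValueError("noise_sd_m must be >= 0")
        if self.day_activity_multiplier < 0:
            raise ValueError("day_activity_multiplier must be >= 0")
        if self.interval_s <= 0 or self.duration_days <= 0:
            raise ValueError("interval_s and duration_days must be > 0")
        if abs(self.origin_lat) > 85:
            raise ValueError("|origin_lat| must be <= 85")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationParams":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)
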