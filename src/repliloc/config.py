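"""Pipeline configuration: typed defaults, TOML loading, validation.

The configuration is a tree of frozen dataclasses.  A plain-text TOML file
may override any subset of fields; unknown keys are rejected with an error
naming the offending key, and a loaded config round-trips losslessly
through :func:`to_dict`.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

from .model import ReplicationModelParams

__all__ = [
    "ConfigError",
    "GrowthConfig",
    "ScheduleConfig",
    "ReplisomeConfig",
    "LocusConfig",
    "NoiseConfig",
    "RegistrationConfig",
    "TrackingConfig",
    "AnalysisConfig",
    "PipelineConfig",
    "load_config",
    "to_dict",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class GrowthConfig:
    """Single-cell growth, division and initiation-threshold parameters.

    Cells grow exponentially in area with per-cell rate noise and divide
    when their area crosses a sizer threshold ``division_factor *
    birth_area_mean`` (lognormal noise).  Replication initiates when the
    area crosses ``a_init`` (lognormal noise); the defaults put initiation
    shortly after birth so a full C-period fits inside one generation.
    """

    birth_area_mean: float = 2.0      # µm²
    growth_rate_cv: float = 0.05      # per-cell CV on mu
    division_factor: float = 2.0      # sizer threshold = factor * birth_area_mean
    division_cv: float = 0.1          # lognormal CV on the division threshold
    init_area_cv: float = 0.02        # lognormal CV on the initiation threshold
    width_um: float = 1.0             # constant cell width; A = L * W

    def validate(self) -> None:
        for key in ("birth_area_mean", "division_factor", "width_um"):
            if not getattr(self, key) > 0:
                raise ConfigError(f"growth.{key} must be > 0, got {getattr(self, key)}")
        for key in ("growth_rate_cv", "division_cv", "init_area_cv"):
            if getattr(self, key) < 0:
                raise ConfigError(f"growth.{key} must be >= 0, got {getattr(self, key)}")


@dataclass(frozen=True)
class ScheduleConfig:
    """Imaging schedule: 1/min frames with paired frames 1 s later."""

    duration_min: float = 300.0
    frame_interval_min: float = 1.0
    doublet_offset_s: float = 1.0
    n_traps: int = 56                 # independent mother-machine channels
    trap_spacing_um: float = 6.0

    def validate(self) -> None:
        if not self.duration_min > 0:
            raise ConfigError(f"schedule.duration_min must be > 0, got {self.duration_min}")
        if not self.frame_interval_min > 0:
            raise ConfigError(
                f"schedule.frame_interval_min must be > 0, got {self.frame_interval_min}"
            )
        if not 0 < self.doublet_offset_s < 60 * self.frame_interval_min:
            raise ConfigError(
                f"schedule.doublet_offset_s must lie in (0, frame interval), "
                f"got {self.doublet_offset_s}"
            )
        if self.n_traps < 1:
            raise ConfigError(f"schedule.n_traps must be >= 1, got {self.n_traps}")


@dataclass(frozen=True)
class ReplisomeConfig:
    """Replisome confinement: stationary OU SDs and correlation time.

    The stationary SDs are the confinement widths; the RMSD plateau of the
    process is sqrt(2) times these (0.25 / 0.12 µm for the defaults).
    """

    sigma_long: float = 0.177         # µm, plateau/sqrt(2)
    sigma_short: float = 0.085        # µm
    tau_min: float = 3.0              # OU correlation time

    def validate(self) -> None:
        if self.sigma_long < 0 or self.sigma_short < 0:
            raise ConfigError("replisome sigma values must be >= 0")
        if not self.tau_min > 0:
            raise ConfigError(f"replisome.tau_min must be > 0, got {self.tau_min}")


@dataclass(frozen=True)
class LocusConfig:
    """One FROS-labeled locus per simulated experiment.

    States are parameterized by their 1-s per-axis step SDs; the generator
    converts these to OU stationary SDs given ``tau_min``.  The replicating
    state defaults to the replisome's implied 1-s step so that a locus being
    replicated moves like the replisome.
    """

    name: str = "Ori"
    alpha: float = 0.014649           # 34 kb / 2321 kb
    tau_min: float = 1.0
    step_sd_long: float = 0.035       # µm per 1-s step, home/relocating/segregating
    step_sd_short: float = 0.018
    replicating_step_sd_long: float | None = None   # None -> replisome-implied
    replicating_step_sd_short: float | None = None
    home_fraction: float | None = None  # None -> -(0.25 + 0.25*alpha)
    anchored: bool = False            # Ter-like: copies stay at mid-cell
    home_side: str = "new"            # new | old | random (subpopulation structure)
    lead_time_min: float = 10.0       # relocation starts this long before replication
    dwell_min: float = 4.0            # colocalized-with-replisome dwell
    segregation_min: float = 10.0     # ramp of the two copies to daughter homes

    def validate(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError(f"locus.alpha must lie in [0, 1], got {self.alpha}")
        if not self.tau_min > 0:
            raise ConfigError(f"locus.tau_min must be > 0, got {self.tau_min}")
        for key in ("step_sd_long", "step_sd_short"):
            if getattr(self, key) < 0:
                raise ConfigError(f"locus.{key} must be >= 0")
        for key in ("lead_time_min", "dwell_min", "segregation_min"):
            if getattr(self, key) < 0:
                raise ConfigError(f"locus.{key} must be >= 0")
        if self.home_side not in ("new", "old", "random"):
            raise ConfigError(f"locus.home_side must be new|old|random, got {self.home_side!r}")
        if self.home_fraction is not None and not -0.5 <= self.home_fraction <= 0.5:
            raise ConfigError(
                f"locus.home_fraction must lie in [-0.5, 0.5], got {self.home_fraction}"
            )

    def resolved_home_fraction(self) -> float:
        """Birth home as a long-axis fraction (negative = new pole)."""
        if self.home_fraction is not None:
            return self.home_fraction
        if self.anchored:
            return -0.5
        return -(0.25 + 0.25 * self.alpha)


@dataclass(frozen=True)
class NoiseConfig:
    """Localization noise and detection misses."""

    loc_sd_replisome: float = 0.02    # µm, isotropic Gaussian
    loc_sd_locus: float = 0.02
    miss_prob: float = 0.02

    def validate(self) -> None:
        if self.loc_sd_replisome < 0 or self.loc_sd_locus < 0:
            raise ConfigError("localization SDs must be >= 0")
        if not 0.0 <= self.miss_prob < 1.0:
            raise ConfigError(f"noise.miss_prob must lie in [0, 1), got {self.miss_prob}")


@dataclass(frozen=True)
class RegistrationConfig:
    """Chromatic offset between the locus and replisome channels.

    The generator shifts locus-channel coordinates by (dx, dy) and emits a
    grid of fiducial landmarks carrying the same transform, so that
    landmark registration is exercised end to end.
    """

    dx_um: float = 0.03
    dy_um: float = -0.02
    grid_n: int = 5                   # grid_n x grid_n fiducials
    grid_spacing_um: float = 5.0
    jitter_sd_um: float = 0.005

    def validate(self) -> None:
        if self.grid_n < 2:
            raise ConfigError(f"registration.grid_n must be >= 2, got {self.grid_n}")
        if self.jitter_sd_um < 0:
            raise ConfigError("registration.jitter_sd_um must be >= 0")


@dataclass(frozen=True)
class TrackingConfig:
    """Linker and initiation-detection parameters."""

    max_disp_um: float = 0.5          # hard link gate between consecutive frames
    max_gap: int = 2                  # frames a trajectory may go undetected
    min_lifetime: int = 5             # frames for a start to count as initiation
    exclusion_radius_um: float = 0.5  # suppress re-detections near existing foci
    doublet_gate_um: float = 0.3      # gate when linking 1-s frame doublets
    pair_max_distance_um: float = 1.0  # gate for replisome-locus pairing

    def validate(self) -> None:
        for key in ("max_disp_um", "exclusion_radius_um", "doublet_gate_um",
                    "pair_max_distance_um"):
            if not getattr(self, key) > 0:
                raise ConfigError(f"tracking.{key} must be > 0")
        if self.max_gap < 0:
            raise ConfigError(f"tracking.max_gap must be >= 0, got {self.max_gap}")
        if self.min_lifetime < 1:
            raise ConfigError(f"tracking.min_lifetime must be >= 1, got {self.min_lifetime}")


@dataclass(frozen=True)
class AnalysisConfig:
    """Binning, windows and estimator settings."""

    area_bin_width: float = 0.25      # µm²
    area_min: float = 1.75
    area_max: float = 4.25
    spatial_bin_um: float = 0.1
    long_half_extent_um: float = 2.5
    short_half_extent_um: float = 0.6
    rmsd_window_min: float = 20.0
    plateau_lag_min: float = 10.0
    plateau_lag_max: float = 20.0
    min_count_exclusive: int = 4      # spatial bins with <= this many steps are masked
    smoothing_bins: int = 3
    n_bootstrap: int = 200
    min_fit_count: int = 10

    def validate(self) -> None:
        if not self.area_bin_width > 0 or not self.spatial_bin_um > 0:
            raise ConfigError("bin widths must be > 0")
        if not self.area_min < self.area_max:
            raise ConfigError("analysis.area_min must be < analysis.area_max")
        if not 0 <= self.plateau_lag_min < self.plateau_lag_max:
            raise ConfigError("plateau lag window must be ordered and non-negative")
        if self.min_count_exclusive < 0:
            raise ConfigError("analysis.min_count_exclusive must be >= 0")
        if self.smoothing_bins < 1 or self.smoothing_bins % 2 == 0:
            raise ConfigError("analysis.smoothing_bins must be an odd integer >= 1")
        if self.n_bootstrap < 0:
            raise ConfigError("analysis.n_bootstrap must be >= 0")


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration for simulate -> track -> analyze -> report."""

    model: ReplicationModelParams = field(default_factory=ReplicationModelParams)
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    replisome: ReplisomeConfig = field(default_factory=ReplisomeConfig)
    locus: LocusConfig = field(default_factory=LocusConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 1
    outdir: str = "results/run"

    def validate(self) -> "PipelineConfig":
        for section in ("growth", "schedule", "replisome", "locus", "noise",
                        "registration", "tracking", "analysis"):
            getattr(self, section).validate()
        # ReplicationModelParams validates in __post_init__.
        if self.seed < 0:
            raise ConfigError(f"seed must be >= 0, got {self.seed}")
        return self


_SECTION_TYPES: dict[str, type] = {
    "model": ReplicationModelParams,
    "growth": GrowthConfig,
    "schedule": ScheduleConfig,
    "replisome": ReplisomeConfig,
    "locus": LocusConfig,
    "noise": NoiseConfig,
    "registration": RegistrationConfig,
    "tracking": TrackingConfig,
    "analysis": AnalysisConfig,
}


def _build_section(name: str, cls: type, data: dict[str, Any]):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in [{name}]: {', '.join(sorted(unknown))}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{name}] section: {exc}") from exc


def config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    """Build a validated :class:`PipelineConfig` from a nested dict."""
    data = dict(data)
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            section = data.pop(name)
            if not isinstance(section, dict):
                raise ConfigError(f"[{name}] must be a table/section")
            kwargs[name] = _build_section(name, cls, section)
    for scalar in ("seed", "outdir"):
        if scalar in data:
            kwargs[scalar] = data.pop(scalar)
    if data:
        raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(data))}")
    return PipelineConfig(**kwargs).validate()


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a TOML config file."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return config_from_dict(raw)


def to_dict(config: PipelineConfig) -> dict[str, Any]:
    """Nested plain-dict view of a config (for echo files and round trips)."""
    out: dict[str, Any] = {}
    for f in fields(config):
        value = getattr(config, f.name)
        if dataclasses.is_dataclass(value):
            out[f.name] = dataclasses.asdict(value)
        else:
            out[f.name] = value
    return out


def locus_step_to_sigma(step_sd: float, tau_min: float, dt_min: float) -> float:
    """OU stationary SD producing a given per-axis step SD at lag ``dt_min``."""
    return step_sd / math.sqrt(2.0 - 2.0 * math.exp(-dt_min / tau_min))


def sigma_to_step(sigma: float, tau_min: float, dt_min: float) -> float:
    """Per-axis step SD at lag ``dt_min`` of an OU with stationary SD ``sigma``."""
    return sigma * math.sqrt(2.0 - 2.0 * math.exp(-dt_min / tau_min))
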