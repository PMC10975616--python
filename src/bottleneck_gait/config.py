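"""Analysis configuration.

All thresholds, windows, bins and grids used by the measurement chain live in
one dataclass so that a run of the pipeline is fully described by a single
config file.  The defaults are the values used throughout the experimental
protocol this package implements:

* 0.5 s centred running-mean windows for speed, acceleration and movement
  direction,
* deceleration thresholds of 1 s (duration) and -0.0075 m/s^2 (amplitude, a
  3-sigma bound on straight-walking acceleration noise),
* straight-walking phase between 3.5 m and 1.5 m before crossing,
* 0.1 m profile bins on [-1 m, 4 m],
* R_crit grid of 180 points on [0.8, 2.6] with 0.05-wide intervals at a 0.95
  significance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    # resampling / geometry
    sample_rate_hz: float = 60.0
    crossing_max_abs_y: float = 0.5     # m; farther than this -> "no crossing"

    # speed (path-distance running mean)
    speed_window_s: float = 0.5
    mean_speed_radius_m: float = 3.0
    vmax_window_m: tuple[float, float] = (0.0, 3.5)

    # deceleration
    decel_duration_threshold_s: float = 1.0
    decel_amplitude_threshold: float = -0.0075   # m/s^2, negative
    decel_window_m: tuple[float, float] = (0.0, 3.5)
    decel_amplitude_magnitude: bool = True   # compare |a| against |threshold|

    # straight-walking phase (baseline window), path distance before crossing
    straight_window_m: tuple[float, float] = (1.5, 3.5)

    # rotation
    rotation_window_s: float = 0.5
    onset_sigma_factor: float = 3.0
    onset_search_max_d: float = 1.5
    onset_center_straight: bool = True
    min_straight_samples: int = 10
    min_com_displacement_m: float = 1e-3

    # profiles
    profile_bin_m: float = 0.1
    profile_range_m: tuple[float, float] = (-1.0, 4.0)

    # steps
    heel_threshold: float | None = None      # absolute m/s; None -> relative
    heel_threshold_rel: float = 0.2          # fraction of 95th pct heel speed
    min_stance_s: float = 0.1
    heel_speed_smooth_s: float = 0.15
    heel_speed_norm: str = "l1"              # "l1" (sum of |vx|,|vy|) or "l2"
    stance_polarity: str = "below"           # "below": strike when speed drops

    # aggregate statistics
    rcrit_grid: tuple[float, float, int] = (0.8, 2.6, 180)
    rcrit_interval: float = 0.05
    significance_level: float = 0.95
    r_split: float = 1.3
    correlation_method: str = "pearson"      # or "spearman"
    crossing_side_from: str = "angle"        # or "sign": infer side from x_cross

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f: raw[f] for f in raw if f in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        # YAML round-trips tuples as lists
        for name in ("vmax_window_m", "decel_window_m", "straight_window_m",
                     "profile_range_m", "rcrit_grid"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg
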