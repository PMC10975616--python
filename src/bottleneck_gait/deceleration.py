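"""Deceleration point and five-way categorisation of braking behaviour.

Contiguous samples of negative smoothed acceleration in the 3.5–0 m
pre-crossing window are grouped and judged by duration and magnitude against
two thresholds: 1 s (duration) and -0.0075 m/s^2 (amplitude; three standard
deviations of straight-walking acceleration noise).  If any group lasts
longer than one second the first such group is evaluated, otherwise the first
group; 'none at all' means the window holds no negative sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import centered_running_mean, speed_along_path

CATEGORIES = ("long_strong", "short_strong", "long_weak", "none", "none_at_all")


@dataclass(frozen=True)
class DecelThresholds:
    duration_threshold_s: float = 1.0
    amplitude_threshold: float = -0.0075      # m/s^2
    window_m: tuple[float, float] = (0.0, 3.5)
    magnitude_comparison: bool = True         # 'larger' read as larger magnitude

    def __post_init__(self) -> None:
        if not self.duration_threshold_s > 0:
            raise ValueError("duration threshold must be > 0")
        if not self.amplitude_threshold < 0:
            raise ValueError("amplitude threshold must be negative")


@dataclass
class DecelerationResult:
    category: str
    decel_point_d: float | None          # undefined only for 'none_at_all'
    span: tuple[float, float] | None     # (t_start, t_end) of the rated group

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.decel_point_d is None) != (self.category == "none_at_all"):
            raise ValueError("decel point defined iff category != none_at_all")


def smooth_acceleration(v: np.ndarray, times: np.ndarray,
                        window: float = 0.5) -> np.ndarray:
    """Smoothed acceleration: central difference of the speed followed by the
    same centred shrinking-window running mean used for the speed itself.

    Exact on affine speed signals.
    """
    v = np.asarray(v, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(v) < 3:
        raise ValueError("need >= 3 samples for acceleration")
    a_raw = np.gradient(v, times)
    return centered_running_mean(a_raw, times, window)


def group_negative(a: np.ndarray, times: np.ndarray, d: np.ndarray,
                   window: tuple[float, float] = (0.0, 3.5)) -> list[np.ndarray]:
    """Maximal contiguous runs of strictly negative acceleration, restricted to
    samples with ``window[0] <= d <= window[1]``, in time order.

    Returns index arrays into the full per-sample arrays.
    """
    a = np.asarray(a, dtype=float)
    d = np.asarray(d, dtype=float)
    if not (len(a) == len(times) == len(d)):
        raise ValueError("a/times/d length mismatch")
    neg = (a < 0) & (d >= window[0]) & (d <= window[1])
    groups: list[np.ndarray] = []
    idx = np.nonzero(neg)[0]
    if len(idx) == 0:
        return groups
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    for chunk in np.split(idx, breaks + 1):
        groups.append(chunk)
    return groups


def _group_duration(group: np.ndarray, times: np.ndarray, dt: float) -> float:
    # one sample period added so a single sample has nonzero duration
    return float(times[group[-1]] - times[group[0]]) + dt


def classify_deceleration(groups: list[np.ndarray], a: np.ndarray,
                          times: np.ndarray, d: np.ndarray,
                          thresholds: DecelThresholds = DecelThresholds()
                          ) -> DecelerationResult:
    """Rate the selected negative-acceleration group.

    Selection: the first group lasting longer than the duration threshold if
    one exists, otherwise the first group.  Categories:

    * ``long_strong``  — longer than 1 s, some sample at or beyond the
      amplitude threshold;
    * ``short_strong`` — 1 s or shorter, some sample at or beyond it;
    * ``long_weak``    — longer than 1 s, no sample beyond it;
    * ``none``         — 1 s or shorter and weak (deceleration point is still
      the first sample of the first negative group);
    * ``none_at_all``  — no negative sample in the window at all.
    """
    if len(groups) == 0:
        return DecelerationResult(category="none_at_all", decel_point_d=None,
                                  span=None)
    times = np.asarray(times, dtype=float)
    dt = float(np.median(np.diff(times)))
    durations = [_group_duration(g, times, dt) for g in groups]
    selected = None
    for g, dur in zip(groups, durations):
        if dur > thresholds.duration_threshold_s:
            selected = (g, dur)
            break
    if selected is None:
        selected = (groups[0], durations[0])
    g, dur = selected
    if thresholds.magnitude_comparison:
        strong = bool(np.any(a[g] <= thresholds.amplitude_threshold))
    else:  # literal 'larger than' on the signed value
        strong = bool(np.any(a[g] > thresholds.amplitude_threshold))
    long = dur > thresholds.duration_threshold_s
    if long and strong:
        cat = "long_strong"
    elif (not long) and strong:
        cat = "short_strong"
    elif long:
        cat = "long_weak"
    else:
        cat = "none"
    point_group = g if cat != "none" else groups[0]
    return DecelerationResult(
        category=cat,
        decel_point_d=float(d[point_group[0]]),
        span=(float(times[g[0]]), float(times[g[-1]])),
    )


def amplitude_threshold_from_straight(a: np.ndarray, d: np.ndarray,
                                      straight: tuple[float, float] = (1.5, 3.5)
                                      ) -> float:
    """Amplitude threshold as minus three standard deviations of the smoothed
    acceleration over the straight-walking window."""
    a = np.asarray(a, dtype=float)
    d = np.asarray(d, dtype=float)
    mask = (d >= straight[0]) & (d <= straight[1]) & np.isfinite(a)
    if not np.any(mask):
        raise ValueError("straight-walking window is empty")
    return float(-3.0 * np.std(a[mask]))


def deceleration_histogram(results: pd.DataFrame) -> pd.DataFrame:
    """Counts of deceleration categories per (angle, motivation).

    ``results`` needs columns ``angle_deg``, ``motivation`` and
    ``decel_category``.  Counts sum to the number of runs.
    """
    if len(results) == 0:
        raise ValueError("no results")
    counts = (results.groupby(["angle_deg", "motivation", "decel_category"])
              .size().rename("count").reset_index())
    return counts
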