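"""Shoulder-rotation signal, onset detection and maximum amplitude.

The shoulder line points from the right to the left acromion.  Rotated
clockwise by 90 deg it gives the facing direction; the rotation angle
``gamma`` is the signed angle from the movement direction (the COM chord over
a 0.5 s window around the current sample, shrinking one-sidedly at the
trajectory edges) to the facing direction.  ``gamma = 0`` when the shoulder
line is perpendicular to the movement direction, positive for a left turn
(mathematically positive sense), negative for a right turn.

The onset of rotation is the first sample past the straight-walking window
where ``|gamma|`` (after removing the straight-walking mean) exceeds three
times its straight-walking standard deviation; the maximum is the largest
excursion after the onset, reported with its sign and location.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory_model import PointSeries


@dataclass
class RotationEvents:
    onset_d: float
    onset_t: float
    max_amplitude: float       # deg, signed: + left turn, - right turn
    max_d: float               # m, negative = after crossing
    max_t: float
    sigma_straight: float      # deg
    mean_straight: float       # deg


def shoulder_rotation(shoulder_left: PointSeries, shoulder_right: PointSeries,
                      com: PointSeries, window: float = 0.5,
                      min_displacement: float = 1e-3) -> np.ndarray:
    """Per-sample shoulder rotation in degrees, NaN where the COM is (nearly)
    stationary across the whole movement-direction window."""
    t = com.times
    if not (len(shoulder_left.times) == len(shoulder_right.times) == len(t)):
        raise ValueError("series must share one time base")
    h = window / 2.0
    t_lo = np.maximum(t - h, t[0])
    t_hi = np.minimum(t + h, t[-1])
    move = np.column_stack([
        np.interp(t_hi, t, com.xy[:, j]) - np.interp(t_lo, t, com.xy[:, j])
        for j in range(2)
    ])
    line = shoulder_left.xy - shoulder_right.xy        # right -> left shoulder
    facing = np.column_stack([line[:, 1], -line[:, 0]])  # rotate by -90 deg
    cross = move[:, 0] * facing[:, 1] - move[:, 1] * facing[:, 0]
    dot = move[:, 0] * facing[:, 0] + move[:, 1] * facing[:, 1]
    gamma = np.degrees(np.arctan2(cross, dot))
    gamma[np.linalg.norm(move, axis=1) < min_displacement] = np.nan
    return gamma


def straight_stats(gamma: np.ndarray, d: np.ndarray,
                   straight: tuple[float, float] = (1.5, 3.5),
                   min_samples: int = 10,
                   center: bool = True) -> tuple[float, float]:
    """Mean and standard deviation of gamma over the straight-walking window."""
    gamma = np.asarray(gamma, dtype=float)
    d = np.asarray(d, dtype=float)
    mask = (d >= straight[0]) & (d <= straight[1]) & np.isfinite(gamma)
    if np.count_nonzero(mask) < min_samples:
        raise ValueError(
            f"straight-walking window has {np.count_nonzero(mask)} samples "
            f"(< {min_samples})")
    mu = float(np.mean(gamma[mask])) if center else 0.0
    sigma = float(np.std(gamma[mask] - mu))
    return mu, sigma


def rotation_onset(gamma: np.ndarray, d: np.ndarray, times: np.ndarray,
                   straight: tuple[float, float] = (1.5, 3.5),
                   sigma_factor: float = 3.0,
                   search_max_d: float | None = None,
                   min_samples: int = 10,
                   center: bool = True) -> RotationEvents | None:
    """Detect the onset of shoulder rotation, or return ``None``.

    The straight-walking window supplies the baseline mean and sigma; the
    onset is the first sample (in time) with ``d < search_max_d`` where the
    centred rotation magnitude exceeds ``sigma_factor * sigma``.  The search
    region starts where the straight window ends so the baseline cannot
    contain its own trigger.
    """
    if search_max_d is None:
        search_max_d = straight[0]
    mu, sigma = straight_stats(gamma, d, straight, min_samples, center)
    gamma = np.asarray(gamma, dtype=float)
    d = np.asarray(d, dtype=float)
    t_straight_end = times[np.nonzero((d >= straight[0]) & (d <= straight[1]))[0][-1]]
    cand = np.nonzero((d < search_max_d) & (times > t_straight_end)
                      & np.isfinite(gamma)
                      & (np.abs(gamma - mu) > sigma_factor * sigma))[0]
    if len(cand) == 0:
        return None
    i = int(cand[0])
    ev = RotationEvents(onset_d=float(d[i]), onset_t=float(times[i]),
                        max_amplitude=np.nan, max_d=np.nan, max_t=np.nan,
                        sigma_straight=sigma, mean_straight=mu)
    return ev


def max_rotation(gamma: np.ndarray, d: np.ndarray, times: np.ndarray,
                 onset: RotationEvents | None) -> RotationEvents | None:
    """Fill in the maximum rotation after the onset (largest |excursion|,
    earliest on ties), reported signed: positive = left turn."""
    if onset is None:
        return None
    gamma = np.asarray(gamma, dtype=float)
    after = np.nonzero((times >= onset.onset_t) & np.isfinite(gamma))[0]
    if len(after) == 0:
        return None
    centered = gamma[after] - onset.mean_straight
    j = after[int(np.argmax(np.abs(centered)))]
    onset.max_amplitude = float(gamma[j] - onset.mean_straight)
    onset.max_d = float(d[j])
    onset.max_t = float(times[j])
    return onset
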