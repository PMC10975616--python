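"""Heel-strike detection and stance-foot assignment.

Heel speed is the sum of the absolute x and y velocity components (central
differences), lightly smoothed.  A stance phase is a maximal run of samples
below a threshold lasting at least a minimum duration; the heel strike is the
start of the stance phase.  Events from both feet are merged in time order;
if the feet do not alternate around an event time, no foot is assigned (a
missed contact cannot be ruled out).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import centered_running_mean
from .trajectory_model import PointSeries


@dataclass
class StepEvents:
    times: np.ndarray            # strike times, strictly increasing
    labels: list[str]            # 'left' / 'right'
    alternating: bool
    threshold: float             # m/s actually used

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.labels):
            raise ValueError("times/labels length mismatch")


def _heel_speed(heel: PointSeries, norm: str, smooth_s: float) -> np.ndarray:
    t = heel.times
    vx = np.gradient(heel.xy[:, 0], t)
    vy = np.gradient(heel.xy[:, 1], t)
    if norm == "l1":
        speed = np.abs(vx) + np.abs(vy)
    elif norm == "l2":
        speed = np.hypot(vx, vy)
    else:
        raise ValueError(f"unknown norm {norm!r}")
    if smooth_s > 0:
        speed = centered_running_mean(speed, t, smooth_s)
    return speed


def _stance_runs(below: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of maximal runs of True, stop exclusive."""
    padded = np.concatenate([[False], below, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.nonzero(diff == 1)[0]
    stops = np.nonzero(diff == -1)[0]
    return list(zip(starts, stops))


def detect_heel_strikes(heel_left: PointSeries, heel_right: PointSeries,
                        threshold: float | None = None, *,
                        threshold_rel: float = 0.2,
                        min_stance_s: float = 0.1,
                        smooth_s: float = 0.15,
                        norm: str = "l1") -> StepEvents:
    """Detect heel strikes of both feet and merge them in time order.

    With ``threshold=None`` the threshold is set per run to ``threshold_rel``
    times the 95th percentile of the combined heel speed.  Ties in strike time
    (e.g. both feet already standing at the first sample) are broken by the
    earlier stance *end*: the foot that moves first made contact first.
    """
    t = heel_left.times
    if len(heel_right.times) != len(t):
        raise ValueError("heel series must share one time base")
    speeds = {"left": _heel_speed(heel_left, norm, smooth_s),
              "right": _heel_speed(heel_right, norm, smooth_s)}
    combined = np.concatenate(list(speeds.values()))
    if threshold is None:
        threshold = threshold_rel * float(np.percentile(combined, 95))
    if threshold <= 0 or threshold >= combined.max():
        raise ValueError(
            f"threshold too high: {threshold:.3g} m/s >= max heel speed "
            f"{combined.max():.3g} m/s (no swing phases detectable)")
    dt = float(np.median(np.diff(t)))
    events: list[tuple[float, float, str]] = []   # (strike_t, stance_end_t, foot)
    for foot, speed in speeds.items():
        for start, stop in _stance_runs(speed < threshold):
            if (stop - start) * dt >= min_stance_s:
                events.append((float(t[start]), float(t[stop - 1]), foot))
    events.sort(key=lambda e: (e[0], e[1]))
    times = np.array([e[0] for e in events])
    labels = [e[2] for e in events]
    alternating = all(a != b for a, b in zip(labels, labels[1:]))
    return StepEvents(times=times, labels=labels, alternating=alternating,
                      threshold=float(threshold))


def foot_on_floor(events: StepEvents, t_event: float) -> str:
    """Foot on the floor closest in time before ``t_event``.

    Returns ``'left'``, ``'right'`` or ``'none'``: none before the first
    strike, and none when the label of the governing strike repeats the one
    before it (non-alternation implies a possibly missed contact).
    """
    if len(events.times) == 0:
        return "none"
    idx = int(np.searchsorted(events.times, t_event, side="right")) - 1
    if idx < 0:
        return "none"
    if idx >= 1 and events.labels[idx] == events.labels[idx - 1]:
        return "none"
    return events.labels[idx]
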