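"""Per-run path geometry and speed metrics.

The central quantity is the signed *distance to crossing* ``d``: arc length
along the COM trajectory to the crossing sample, positive before the crossing
and negative after.  Speed is estimated from ``d`` with a 0.5 s centred
running mean (the approximate duration of one step), which equals the
two-point difference of ``d`` across the window and is exact on linear
signals.  At the trajectory edges the window shrinks symmetrically, always
including the first or last sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory_model import CrossingResult, PointSeries


def centered_running_mean(y: np.ndarray, times: np.ndarray,
                          window: float) -> np.ndarray:
    """Centred running mean with a symmetrically shrinking window at the edges.

    At index ``i`` the half-width is ``min(window/2, t_i - t_0, t_N - t_i)``
    so the window always stays symmetric around ``t_i``; affine signals pass
    through unchanged.  Assumes a (nominally) uniform time grid.
    """
    y = np.asarray(y, dtype=float)
    times = np.asarray(times, dtype=float)
    n = len(y)
    if n < 1:
        raise ValueError("empty signal")
    dt = float(np.median(np.diff(times))) if n > 1 else 1.0
    k_full = max(int(round(window / 2.0 / dt)), 0)
    idx = np.arange(n)
    k = np.minimum(k_full, np.minimum(idx, n - 1 - idx))
    csum = np.concatenate([[0.0], np.cumsum(y)])
    lo = idx - k
    hi = idx + k
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def compute_crossing(com: PointSeries, *, max_abs_y: float = 0.5) -> CrossingResult:
    """The COM sample closest to the crossing line y = 0 (earliest on ties).

    Side approaches (±90 deg) start next to the crossing line, so the search
    is restricted to the final approach: samples after the last one clearly on
    the approach side (y > ``max_abs_y``).  For trajectories that never leave
    the line's neighbourhood this reduces to the global argmin of |y|.
    """
    y = com.xy[:, 1]
    absy = np.abs(y)
    above = np.nonzero(y > max_abs_y)[0]
    start = int(above[-1]) if len(above) else 0
    i = start + int(np.argmin(absy[start:]))  # argmin picks the earliest tie
    if absy[i] >= max_abs_y:
        raise ValueError(
            f"no crossing: trajectory never reaches |y| < {max_abs_y} m "
            f"(closest approach {absy[i]:.3f} m)")
    return CrossingResult(x_cross=float(com.xy[i, 0]),
                          t_cross=float(com.times[i]), index=i)


def distance_to_crossing(com: PointSeries, crossing: CrossingResult) -> np.ndarray:
    """Signed arc length along the COM path to the crossing sample.

    ``d`` decreases by exactly the per-sample chord length; ``d = 0`` at the
    crossing sample, positive before, negative after.
    """
    seg = np.linalg.norm(np.diff(com.xy, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return arc[crossing.index] - arc


def speed_along_path(d: np.ndarray, times: np.ndarray,
                     window: float = 0.5) -> np.ndarray:
    """Speed from the centred running mean of the distance to crossing.

    ``v(t) = (d(t-h') - d(t+h')) / (2 h')`` with
    ``h' = min(window/2, t - t_first, t_last - t)``; this equals the mean of
    the instantaneous path speed over the shrunk window.  At the two boundary
    samples (where ``h' = 0``) a one-sided difference to the neighbouring
    sample is used.
    """
    d = np.asarray(d, dtype=float)
    times = np.asarray(times, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need >= 2 samples")
    if len(times) != n:
        raise ValueError("d/times length mismatch")
    dt = float(np.median(np.diff(times)))
    if window <= dt:
        raise ValueError(f"window {window} s must exceed the sample spacing {dt} s")
    h = np.minimum(window / 2.0, np.minimum(times - times[0], times[-1] - times))
    v = np.empty(n)
    interior = h > 0
    ti = times[interior]
    hi = h[interior]
    v[interior] = (np.interp(ti - hi, times, d) - np.interp(ti + hi, times, d)) / (2 * hi)
    v[0] = (d[0] - d[1]) / (times[1] - times[0])
    v[-1] = (d[-2] - d[-1]) / (times[-1] - times[-2])
    return v


def mean_speed(com: PointSeries, crossing: CrossingResult,
               radius: float = 3.0) -> float:
    """Mean speed from entering a 3 m radius around the origin until crossing.

    Path length over elapsed time, starting at the first sample whose
    Euclidean distance to the bottleneck centre is <= ``radius`` (this
    excludes the acceleration phase) and ending at the crossing sample.
    """
    r = np.linalg.norm(com.xy, axis=1)
    inside = np.nonzero(r <= radius)[0]
    if len(inside) == 0:
        raise ValueError(f"COM never enters the {radius} m radius")
    i0 = int(inside[0])
    i1 = crossing.index
    if i1 <= i0:
        raise ValueError("crossing precedes entry into the radius")
    seg = np.linalg.norm(np.diff(com.xy[i0:i1 + 1], axis=0), axis=1)
    return float(np.sum(seg) / (com.times[i1] - com.times[i0]))


def find_vmax_vmin(v: np.ndarray, d: np.ndarray, times: np.ndarray,
                   window: tuple[float, float] = (0.0, 3.5)
                   ) -> tuple[float, float, float, float]:
    """Maximum speed in the pre-crossing window and minimum speed after it.

    ``vmax`` is the maximum of ``v`` over samples with
    ``window[0] <= d <= window[1]`` (straight-walking start to crossing);
    ``vmin`` the minimum over samples from the time of ``vmax`` to the end of
    the walking path.  Ties pick the earliest sample.

    Returns ``(vmax, d_at_vmax, t_at_vmax, vmin)``.
    """
    v = np.asarray(v, dtype=float)
    d = np.asarray(d, dtype=float)
    lo, hi = window
    if d.max() < hi:
        raise ValueError(f"run does not cover d = {hi} m (max d = {d.max():.2f})")
    if d.min() > lo:
        raise ValueError(f"run does not reach d = {lo} m (min d = {d.min():.2f})")
    mask = (d >= lo) & (d <= hi)
    idx = np.nonzero(mask)[0]
    i_max = idx[int(np.argmax(v[idx]))]
    vmax = float(v[i_max])
    after = np.arange(i_max, len(v))
    vmin = float(np.min(v[after]))
    return vmax, float(d[i_max]), float(times[i_max]), vmin


@dataclass
class ProfileBins:
    """Per-bin means of a signal against distance to crossing."""

    centers: np.ndarray
    means: np.ndarray    # NaN where a bin is empty
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)


def bin_profile(values: np.ndarray, d: np.ndarray, bin: float = 0.1,
                range: tuple[float, float] = (-1.0, 4.0)) -> ProfileBins:
    """Mean of ``values`` in fixed-width bins of distance to crossing."""
    values = np.asarray(values, dtype=float)
    d = np.asarray(d, dtype=float)
    if len(values) != len(d):
        raise ValueError("values/d length mismatch")
    lo, hi = range
    n_bins = int(round((hi - lo) / bin))
    edges = lo + np.arange(n_bins + 1) * bin
    centers = edges[:-1] + bin / 2.0
    ok = np.isfinite(values) & (d >= lo) & (d < hi)
    which = np.floor((d[ok] - lo) / bin).astype(int)
    which = np.clip(which, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=values[ok], minlength=n_bins)
    means = np.full(n_bins, np.nan)
    nz = counts > 0
    means[nz] = sums[nz] / counts[nz]
    return ProfileBins(centers=centers, means=means, counts=counts)


def mean_profile(profiles: list[ProfileBins]) -> ProfileBins:
    """Two-stage mean: per-run bin means first, then an unweighted mean per bin.

    Bins are averaged across runs with equal weight regardless of how many
    samples each run contributed; bins empty in a run do not enter that bin's
    cross-run mean.
    """
    if not profiles:
        raise ValueError("no profiles")
    centers = profiles[0].centers
    for p in profiles[1:]:
        if not np.allclose(p.centers, centers):
            raise ValueError("profiles have mismatched bins")
    stack = np.vstack([p.means for p in profiles])
    counts = np.sum(np.isfinite(stack), axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, np.nanmean(stack, axis=0), np.nan)
    return ProfileBins(centers=centers.copy(), means=means, counts=counts)
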