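import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bottleneck_gait import kinematics as kin
from bottleneck_gait.trajectory_model import PointSeries


def series(xy):
    xy = np.asarray(xy, dtype=float)
    return PointSeries(times=np.arange(len(xy)) / 60.0, positions=xy)


# ------------------------------------------------------------- crossing

def test_crossing_picks_min_abs_y():
    y = [0.5, 0.2, 0.2, -0.1]
    c = kin.compute_crossing(series(np.column_stack([np.zeros(4), y])))
    assert c.index == 3


def test_crossing_tie_breaks_earliest():
    y = [0.6, 0.2, -0.2, -0.4]
    c = kin.compute_crossing(series(np.column_stack([np.zeros(4), y])))
    assert c.index == 1


def test_crossing_matches_brute_force_on_noisy_diagonal():
    rng = np.random.default_rng(7)
    n = 400
    y = np.linspace(2, -2, n) + rng.normal(0, 0.01, n)
    x = np.linspace(0, 1, n)
    com = series(np.column_stack([x, y]))
    c = kin.compute_crossing(com)
    assert c.index == int(np.argmin(np.abs(y)))
    assert c.x_cross == x[c.index]


def test_crossing_error_when_far():
    y = np.linspace(5, 1, 50)
    with pytest.raises(ValueError, match="no crossing"):
        kin.compute_crossing(series(np.column_stack([np.zeros(50), y])))


# ----------------------------------------------------- distance to crossing

def test_distance_is_arc_length_not_euclidean():
    # L-shaped path: 1 m sideways at y = 1, then 1 m down to the crossing.
    # At the start the Euclidean offset to the crossing is sqrt(2); the
    # path-length definition gives 2.0.
    n = 61
    leg1 = np.column_stack([np.linspace(0.0, 1.0, n), np.ones(n)])
    leg2 = np.column_stack([np.ones(n - 1), np.linspace(1.0, 0.0, n)[1:]])
    xy = np.vstack([leg1, leg2])
    com = series(xy)
    crossing = kin.compute_crossing(com)
    d = kin.distance_to_crossing(com, crossing)
    corner = n - 1
    assert crossing.index == len(xy) - 1
    assert d[corner] == pytest.approx(1.0, abs=1e-12)
    assert d[0] == pytest.approx(2.0, abs=1e-12)


def test_distance_constant_speed():
    com = series(np.column_stack([np.zeros(241), np.linspace(2, -2, 241)]))
    c = kin.compute_crossing(com)
    d = kin.distance_to_crossing(com, c)
    t = com.times
    i = np.argmin(np.abs(t - (t[c.index] - 2.0)))
    assert d[i] == pytest.approx(2.0, abs=1e-9)


def test_distance_matches_chord_sum_on_random_walk():
    rng = np.random.default_rng(3)
    xy = np.cumsum(rng.normal(0, 0.01, size=(300, 2)), axis=0)
    xy[:, 1] += np.linspace(1.5, -1.5, 300)  # drift through the crossing line
    com = series(xy)
    c = kin.compute_crossing(com)
    d = kin.distance_to_crossing(com, c)
    # brute-force chord sums
    for i in [0, 10, 149, 200, 299]:
        lo, hi = sorted((i, c.index))
        expected = np.sum(np.linalg.norm(np.diff(xy[lo:hi + 1], axis=0), axis=1))
        assert abs(abs(d[i]) - expected) < 1e-12


# --------------------------------------------------------------- speed

def test_speed_constant_everywhere_including_edges():
    t = np.arange(200) / 60.0
    d = 5.0 - 1.5 * t
    v = kin.speed_along_path(d, t, window=0.5)
    np.testing.assert_allclose(v, 1.5, atol=1e-9)


def test_speed_step_window_midpoint():
    # speed steps 1.0 -> 2.0 at t0: the symmetric window mean at t0 is 1.5
    t = np.arange(241) / 60.0
    t0 = t[120]
    d0 = 6.0
    d = np.where(t <= t0, d0 - 1.0 * t, d0 - t0 - 2.0 * (t - t0))
    v = kin.speed_along_path(d, t, window=0.5)
    assert v[120] == pytest.approx(1.5, abs=1e-9)


def test_speed_matches_brute_force_window_mean():
    rng = np.random.default_rng(5)
    t = np.arange(300) / 60.0
    inst = 1.2 + 0.5 * np.abs(np.sin(2 * np.pi * t / 2.3)) + rng.normal(0, 0.01, 300)
    d = 10.0 - np.concatenate([[0.0], np.cumsum((inst[1:] + inst[:-1]) / 2 * np.diff(t))])
    v = kin.speed_along_path(d, t, window=0.5)
    for i in range(1, 299):
        h = min(0.25, t[i] - t[0], t[-1] - t[i])
        expected = (np.interp(t[i] - h, t, d) - np.interp(t[i] + h, t, d)) / (2 * h)
        assert abs(v[i] - expected) < 1e-10


def test_speed_window_too_small_rejected():
    t = np.arange(100) / 60.0
    with pytest.raises(ValueError):
        kin.speed_along_path(5.0 - t, t, window=0.01)


# ----------------------------------------------------------- mean speed

def test_mean_speed_excludes_acceleration_outside_radius():
    # accelerate from 0.5 to 1.5 m/s before r=3, hold 1.5 inside
    rate = 60.0
    t_acc = np.arange(0, 2.0, 1 / rate)
    v_acc = 0.5 + 0.5 * t_acc
    y_acc = 5.0 - np.cumsum(v_acc) / rate
    y0 = y_acc[-1]
    assert y0 > 3.0
    t_cr = np.arange(1, int((y0 + 1) * rate / 1.5)) / rate
    y_cr = y0 - 1.5 * t_cr
    y = np.concatenate([y_acc, y_cr])
    com = series(np.column_stack([np.zeros(len(y)), y]))
    c = kin.compute_crossing(com)
    assert kin.mean_speed(com, c, radius=3.0) == pytest.approx(1.5, rel=1e-3)


def test_mean_speed_error_outside_radius():
    from bottleneck_gait.trajectory_model import CrossingResult
    com = series(np.column_stack([np.full(50, 10.0), np.linspace(5, 4, 50)]))
    with pytest.raises(ValueError, match="never enters"):
        kin.mean_speed(com, CrossingResult(x_cross=10.0, t_cross=0.8, index=49))


# ----------------------------------------------------------- vmax / vmin

def _vprofile(vfun, n=600, d0=6.0):
    t = np.arange(n) / 60.0
    v = vfun(t)
    d = d0 - np.concatenate([[0.0], np.cumsum((v[1:] + v[:-1]) / 2 / 60.0)])
    return v, d, t


def test_vmax_window_excludes_outside_peak():
    # main max while d > 3.5 (outside the search window), secondary 1.8 inside
    v, d, t = _vprofile(lambda t: np.where(t < 0.5, 2.5, np.where(t < 3.0, 1.0, 1.8)))
    vmax, d_at, t_at, vmin = kin.find_vmax_vmin(v, d, t)
    assert vmax == pytest.approx(1.8)
    assert d_at <= 3.5


def test_vmax_equal_vmin_for_constant_speed():
    v, d, t = _vprofile(lambda t: np.full_like(t, 1.3))
    vmax, _, _, vmin = kin.find_vmax_vmin(v, d, t)
    assert vmax == vmin == pytest.approx(1.3)


def test_vmax_rising_then_flat_then_drop():
    # accelerate 1.4 m/s^2 x 1.5 s -> plateau 2.1 -> decline to 1.2 after t=3
    def vf(t):
        return np.where(t < 1.5, 1.4 * t, np.where(t < 3.0, 2.1, 1.2))
    t = np.arange(600) / 60.0
    v = vf(t)
    d = 6.5 - np.concatenate([[0.0], np.cumsum((v[1:] + v[:-1]) / 2 / 60.0)])
    vmax, _, t_at, vmin = kin.find_vmax_vmin(v, d, t)
    assert vmax == pytest.approx(2.1)
    assert vmin == pytest.approx(1.2)
    assert t_at >= 1.5


def test_vmax_error_names_missing_window():
    v = np.full(100, 1.0)
    d = np.linspace(3.0, 1.0, 100)   # never reaches 0
    with pytest.raises(ValueError, match="does not"):
        kin.find_vmax_vmin(v, d, np.arange(100) / 60.0)


# ----------------------------------------------------------- profiles

def test_bin_profile_constant_value():
    d = np.linspace(3.95, -0.95, 500)
    p = kin.bin_profile(np.ones(500), d)
    covered = p.counts > 0
    assert covered.sum() == 50
    np.testing.assert_allclose(p.means[covered], 1.0)


def test_mean_profile_is_unweighted_across_runs():
    d1 = np.linspace(3.95, -0.95, 1000)   # many samples
    d2 = np.linspace(3.95, -0.95, 100)    # few samples
    p1 = kin.bin_profile(np.full(1000, 1.0), d1)
    p2 = kin.bin_profile(np.full(100, 2.0), d2)
    mp = kin.mean_profile([p1, p2])
    covered = mp.counts == 2
    np.testing.assert_allclose(mp.means[covered], 1.5)


def test_two_stage_profile_matches_direct_computation():
    rng = np.random.default_rng(11)
    profiles, expected = [], {}
    per_run_means = []
    for _ in range(5):
        n = rng.integers(200, 400)
        d = rng.uniform(-1, 4, n)
        vals = rng.normal(1.5, 0.3, n)
        profiles.append(kin.bin_profile(vals, d))
        # direct oracle
        means = np.full(50, np.nan)
        for b in range(50):
            lo, hi = -1 + 0.1 * b, -1 + 0.1 * (b + 1)
            m = (d >= lo) & (d < hi)
            if m.any():
                means[b] = vals[m].mean()
        per_run_means.append(means)
    mp = kin.mean_profile(profiles)
    oracle = np.nanmean(np.vstack(per_run_means), axis=0)
    ok = np.isfinite(oracle)
    np.testing.assert_allclose(mp.means[ok], oracle[ok], atol=1e-12)


# ------------------------------------------------- running mean property

@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=5, max_value=200), st.integers(min_value=0, max_value=2**31 - 1))
def test_running_mean_matches_brute_force(n, seed):
    rng = np.random.default_rng(seed)
    y = rng.normal(0, 1, n)
    t = np.arange(n) / 60.0
    m = kin.centered_running_mean(y, t, 0.5)
    k_full = 15
    for i in range(n):
        k = min(k_full, i, n - 1 - i)
        assert abs(m[i] - y[i - k:i + k + 1].mean()) < 1e-10


def test_running_mean_exact_on_affine():
    t = np.arange(100) / 60.0
    y = 3.0 - 1.7 * t
    np.testing.assert_allclose(kin.centered_running_mean(y, t, 0.5), y, atol=1e-12)
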