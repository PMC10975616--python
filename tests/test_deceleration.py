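import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bottleneck_gait import deceleration as dec
from bottleneck_gait.pipeline import analyze_run
from bottleneck_gait.synthetic import DECEL_CATEGORIES, generate_run


T = np.arange(400) / 60.0


def test_smooth_acceleration_exact_on_linear_ramp():
    v = 0.2 + 1.4 * T
    a = dec.smooth_acceleration(v, T)
    np.testing.assert_allclose(a[5:-5], 1.4, atol=1e-9)


def test_smooth_acceleration_zero_for_constant_speed():
    a = dec.smooth_acceleration(np.full_like(T, 1.5), T)
    np.testing.assert_allclose(a, 0.0, atol=1e-12)


def test_smooth_acceleration_matches_windowed_analytic_derivative():
    w = 2 * np.pi / 2.0      # 0.5 Hz oscillation
    v = 1.5 + 0.3 * np.sin(w * T)
    a = dec.smooth_acceleration(v, T)
    # oracle: centred running mean of the analytic derivative
    from bottleneck_gait.kinematics import centered_running_mean
    oracle = centered_running_mean(0.3 * w * np.cos(w * T), T, 0.5)
    amp = 0.3 * w
    assert np.max(np.abs(a[2:-2] - oracle[2:-2])) < 0.02 * amp


def test_group_negative_basic_and_window():
    a = np.array([0.1, -0.2, -0.3, 0.1, -0.1])
    d = np.array([3.0, 2.5, 2.0, 1.5, 1.0])
    groups = dec.group_negative(a, np.arange(5) / 60.0, d)
    assert [list(g) for g in groups] == [[1, 2], [4]]
    # samples outside the 3.5-0 m window break and exclude groups
    d2 = np.array([4.0, 2.5, 2.0, 1.5, -0.5])
    groups2 = dec.group_negative(a, np.arange(5) / 60.0, d2)
    assert [list(g) for g in groups2] == [[1, 2]]


def test_group_negative_empty_when_nonnegative():
    a = np.abs(np.sin(T))
    d = np.linspace(3.4, 0.1, len(T))
    assert dec.group_negative(a, T, d) == []


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_group_negative_matches_linear_scan(seed):
    rng = np.random.default_rng(seed)
    n = 120
    a = rng.normal(0, 1, n)
    d = np.linspace(3.8, -0.4, n)
    t = np.arange(n) / 60.0
    groups = dec.group_negative(a, t, d)
    # oracle: linear scan
    oracle, cur = [], []
    for i in range(n):
        if a[i] < 0 and 0 <= d[i] <= 3.5:
            cur.append(i)
        else:
            if cur:
                oracle.append(cur)
            cur = []
    if cur:
        oracle.append(cur)
    assert [list(g) for g in groups] == oracle


def _classify(groups_spec, dt=1 / 60.0):
    """groups_spec: list of (duration_s, min_amplitude).  Builds an a/d/t
    layout with the groups separated by positive samples."""
    a, chunks = [], []
    idx = 0
    for dur, amp in groups_spec:
        a.extend([0.1] * 5)
        idx += 5
        k = max(int(round(dur / dt)), 1)
        g = np.full(k, -0.001)
        g[k // 2] = amp
        a.extend(g)
        chunks.append(list(range(idx, idx + k)))
        idx += k
    a.extend([0.1] * 5)
    a = np.array(a)
    n = len(a)
    t = np.arange(n) * dt
    d = np.linspace(3.4, 0.1, n)
    groups = dec.group_negative(a, t, d)
    return dec.classify_deceleration(groups, a, t, d), d, chunks


@pytest.mark.parametrize("dur,amp,expected", [
    (1.2, -0.02, "long_strong"),
    (0.4, -0.02, "short_strong"),
    (1.5, -0.004, "long_weak"),
    (0.3, -0.003, "none"),
])
def test_classification_rules(dur, amp, expected):
    result, d, chunks = _classify([(dur, amp)])
    assert result.category == expected
    assert result.decel_point_d == pytest.approx(d[chunks[0][0]])


def test_first_long_group_selected_over_earlier_short():
    # short strong group first, then the first >1 s group decides the rating
    result, d, chunks = _classify([(0.4, -0.02), (1.5, -0.004)])
    assert result.category == "long_weak"
    assert result.decel_point_d == pytest.approx(d[chunks[1][0]])


def test_none_at_all_without_groups():
    a = np.full(200, 0.05)
    t = np.arange(200) / 60.0
    d = np.linspace(3.4, 0.1, 200)
    result = dec.classify_deceleration(dec.group_negative(a, t, d), a, t, d)
    assert result.category == "none_at_all"
    assert result.decel_point_d is None


def test_boundary_duration_falls_to_short_branch():
    # exactly the threshold duration is not 'longer than'
    dt = 1 / 60.0
    k = 60  # 60 samples -> duration (59 * dt) + dt = 1.0 s exactly
    a = np.concatenate([np.full(10, 0.1), np.full(k, -0.02), np.full(10, 0.1)])
    t = np.arange(len(a)) * dt
    d = np.linspace(3.4, 0.5, len(a))
    result = dec.classify_deceleration(dec.group_negative(a, t, d), a, t, d)
    assert result.category == "short_strong"


def test_amplitude_threshold_from_straight_noise():
    rng = np.random.default_rng(0)
    n = 4000
    d = np.linspace(3.5, 1.5, n)
    a = rng.normal(0, 0.0025, n)
    thr = dec.amplitude_threshold_from_straight(a, d)
    assert thr == pytest.approx(-0.0075, rel=0.05)
    assert dec.amplitude_threshold_from_straight(np.zeros(n), d) == 0.0


def test_histogram_conserves_counts(clean_config, meta_factory):
    import pandas as pd
    rows = []
    rng = np.random.default_rng(4)
    for i in range(50):
        rows.append({"angle_deg": rng.choice([0, 60]),
                     "motivation": rng.choice(["normal", "hurried"]),
                     "decel_category": rng.choice(DECEL_CATEGORIES)})
    counts = dec.deceleration_histogram(pd.DataFrame(rows))
    assert counts["count"].sum() == 50


@pytest.mark.parametrize("cat_idx", range(5))
def test_noiseless_runs_recover_generated_category(clean_config, meta_factory,
                                                   cat_idx):
    """The five-way classifier recovers the generator's category on all
    margin-guaranteed noiseless runs."""
    probs = [0.0] * 5
    probs[cat_idx] = 1.0
    for angle in (0, 60, -90):
        for motivation in ("normal", "hurried"):
            cfg = clean_config(decel_mixture={(angle, motivation): probs})
            meta = meta_factory(angle=angle, motivation=motivation,
                                run_id=f"cat{cat_idx}")
            for seed in range(3):
                rec, gt = generate_run(cfg, meta, seed)
                res = analyze_run(rec)
                assert res.decel_category == gt.decel_category, \
                    (angle, motivation, seed)
                if gt.decel_point_d is not None:
                    # smoothing shifts the detected point at most ~0.6 s of path
                    assert abs(res.decel_point_d - gt.decel_point_d) < \
                        0.65 * gt.cruise_speed


def test_classifier_invariant_under_mirroring(clean_config, meta_factory):
    from bottleneck_gait.trajectory_model import mirror_run
    cfg = clean_config()
    meta = meta_factory(angle=60, run_id="mir")
    rec, gt = generate_run(cfg, meta, 5)
    res = analyze_run(rec)
    res_m = analyze_run(mirror_run(rec))
    assert res.decel_category == res_m.decel_category
    if res.decel_point_d is not None:
        assert res_m.decel_point_d == pytest.approx(res.decel_point_d, abs=1e-9)
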