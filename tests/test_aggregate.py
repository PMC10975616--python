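import numpy as np
import pandas as pd
import pytest

from bottleneck_gait import aggregate as agg


# ------------------------------------------------------------ exponential fit

def test_exponential_fit_exact_recovery():
    rng = np.random.default_rng(0)
    R = rng.uniform(0.8, 2.6, 40)
    y = 40.0 * np.exp(-3.0 * R) + 5.0
    fit = agg.fit_max_rotation_curve(R, y)
    assert fit.a == pytest.approx(40.0, rel=1e-6)
    assert fit.b == pytest.approx(3.0, rel=1e-6)
    assert fit.d == pytest.approx(5.0, rel=1e-6)
    assert not fit.degenerate


def test_exponential_fit_constant_is_degenerate():
    R = np.linspace(0.8, 2.6, 20)
    fit = agg.fit_max_rotation_curve(R, np.full(20, 7.5))
    assert fit.degenerate
    assert fit.d == pytest.approx(7.5)
    np.testing.assert_allclose(fit(R), 7.5, atol=1e-6)


def test_exponential_fit_noisy_recovery_within_3se():
    rng = np.random.default_rng(12)
    n = 400
    R = rng.uniform(0.8, 2.6, n)
    truth = (60.0, 2.5, 8.0)
    y = truth[0] * np.exp(-truth[1] * R) + truth[2] + rng.normal(0, 3.0, n)
    fit = agg.fit_max_rotation_curve(R, y)
    for name, true_val, est in (("a", truth[0], fit.a), ("b", truth[1], fit.b),
                                ("d", truth[2], fit.d)):
        se = fit.stderr[name]
        assert abs(est - true_val) <= 3 * se, (name, est, true_val, se)


def test_exponential_fit_needs_enough_points():
    with pytest.raises(ValueError):
        agg.fit_max_rotation_curve(np.ones(5), np.ones(5))


# ------------------------------------------------------------ Tukey HSD

def test_tukey_identical_groups_not_significant():
    rng = np.random.default_rng(1)
    g = rng.normal(0, 1, 30)
    table = agg.tukey_hsd({"a": g, "b": g.copy()})
    assert not table["significant"].any()


def test_tukey_separated_groups_significant():
    rng = np.random.default_rng(2)
    table = agg.tukey_hsd({"a": rng.normal(0, 1, 30),
                           "b": rng.normal(5, 1, 30)})
    assert table["significant"].all()


def test_tukey_matches_statsmodels_decisions():
    """Accept/reject decisions agree with an independent implementation
    (statsmodels pairwise_tukeyhsd) on seeded three-group data."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    rng = np.random.default_rng(3)
    groups = {"a": rng.normal(0.0, 1.0, 25),
              "b": rng.normal(0.8, 1.0, 30),
              "c": rng.normal(0.9, 1.0, 20)}
    ours = agg.tukey_hsd(groups, level=0.95)
    data = np.concatenate(list(groups.values()))
    labels = sum([[k] * len(v) for k, v in groups.items()], [])
    sm = pairwise_tukeyhsd(data, labels, alpha=0.05)
    sm_df = pd.DataFrame(sm.summary().data[1:], columns=sm.summary().data[0])
    merged = ours.merge(sm_df, left_on=["group1", "group2"],
                        right_on=["group1", "group2"])
    assert len(merged) == 3
    assert (merged["significant"] == merged["reject"]).all()
    np.testing.assert_allclose(merged["p"], merged["p-adj"].astype(float),
                               atol=1e-3)


def test_tukey_small_group_rejected():
    with pytest.raises(ValueError):
        agg.tukey_hsd({"a": [1.0], "b": [1.0, 2.0]})


# ------------------------------------------------------------ critical point

class _SharpPlateau:
    """Curve that is exactly constant beyond the edge, steep before it."""

    def __init__(self, edge=1.6, plateau=8.0, slope=40.0):
        self.edge, self.plateau, self.slope = edge, plateau, slope

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.plateau + self.slope * np.maximum(self.edge - x, 0.0)


def test_rcrit_locates_constructed_plateau_edge():
    counts = np.full(36, 10.0)
    cp = agg.critical_point(_SharpPlateau(edge=1.6), residual_sd=1.0,
                            group_sizes=counts)
    assert abs(cp.rcrit - 1.6) <= 0.05 + 1e-9


def test_rcrit_constant_curve_is_left_edge():
    fit = agg.FitResult(a=0.0, b=1.0, c=0.0, d=5.0, stderr={},
                        residuals=np.zeros(10))
    cp = agg.critical_point(fit, residual_sd=0.5,
                            group_sizes=np.full(36, 5.0))
    assert cp.rcrit == pytest.approx(0.8)


def test_rcrit_steep_monotone_curve_near_right_end():
    fit = agg.FitResult(a=100.0, b=0.8, c=0.0, d=0.0, stderr={},
                        residuals=np.zeros(10))
    cp = agg.critical_point(fit, residual_sd=1e-4,
                            group_sizes=np.full(36, 10.0))
    assert cp.rcrit >= 2.45


def test_rcrit_monotone_in_decay_rate():
    """A steeper approach to the plateau never increases R_crit."""
    counts = np.full(36, 10.0)
    prev = None
    for b in (2.0, 4.0, 8.0):
        a = 30.0 * np.exp(b * 1.4)
        fit = agg.FitResult(a=a, b=b, c=0.0, d=10.0, stderr={},
                            residuals=np.zeros(10))
        cp = agg.critical_point(fit, residual_sd=1.0, group_sizes=counts)
        if prev is not None:
            assert cp.rcrit <= prev + 1e-9
        prev = cp.rcrit


def test_rcrit_plateau_recovery_across_seeds():
    """Fit + critical point recover a constructed plateau edge within one
    interval width (0.05) across 20 seeded replicates.

    Truth is an exponential decay towards a plateau; the plateau edge is
    defined independently (oracle) as the first 0.05-interval whose mean is
    within the Tukey least-significant difference of the last interval, using
    the true parameters, the known residual sd and the expected per-interval
    counts."""
    from scipy import stats
    a_t, b_t, d_t, sd, n = 60.0, 2.5, 8.0, 1.0, 2000
    grid = np.linspace(0.8, 2.6, 180)
    which = np.clip(((grid - 0.8) / 0.05).astype(int), 0, 35)
    f_true = a_t * np.exp(-b_t * grid) + d_t
    means = np.array([f_true[which == i].mean() for i in range(36)])
    q_crit = stats.studentized_range.ppf(0.95, 36, n - 36)
    lsd = q_crit * sd * np.sqrt(0.5 * 2.0 / (n / 36))
    edge = 0.8 + 0.05 * np.nonzero(means - means[-1] <= lsd)[0][0]

    hits = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        R = rng.uniform(0.8, 2.6, n)
        y = a_t * np.exp(-b_t * R) + d_t + rng.normal(0, sd, n)
        fit = agg.fit_max_rotation_curve(R, y)
        counts = np.histogram(R, bins=36, range=(0.8, 2.6))[0]
        cp = agg.critical_point(fit, fit.residual_sd, counts)
        hits.append(cp.rcrit)
    assert np.all(np.abs(np.array(hits) - edge) <= 0.05 + 1e-9)


def test_rcrit_too_few_intervals():
    fit = _SharpPlateau()
    counts = np.zeros(36)
    counts[3] = 5
    with pytest.raises(ValueError):
        agg.critical_point(fit, 1.0, counts)


# ------------------------------------------------------------ crossing law

def test_crossing_law_exact_recovery_and_shift():
    widths = np.repeat([0.4, 0.5, 0.6, 0.7, 0.8, 1.0], 4)
    sides = np.tile([1, 1, -1, -1], 6)
    x = sides * (0.176 * widths - 0.078)
    law = agg.fit_crossing_model(widths, x, sides)
    assert law.slope == pytest.approx(0.176, abs=1e-12)
    assert law.intercept == pytest.approx(-0.078, abs=1e-12)
    assert law.shift_per_10cm_cm == pytest.approx(1.76, abs=1e-9)


def test_crossing_law_zero_offsets():
    widths = np.repeat([0.4, 1.0], 10)
    law = agg.fit_crossing_model(widths, np.zeros(20), np.ones(20))
    assert law.slope == pytest.approx(0.0, abs=1e-12)
    assert law.intercept == pytest.approx(0.0, abs=1e-12)


def test_crossing_law_noisy_recovery_within_3se():
    rng = np.random.default_rng(9)
    n = 600
    widths = rng.choice([0.4, 0.5, 0.6, 0.7, 0.8, 1.0], n)
    sides = rng.choice([-1, 1], n)
    x = sides * (0.176 * widths - 0.078) + rng.normal(0, 0.05, n)
    law = agg.fit_crossing_model(widths, x, sides)
    assert abs(law.slope - 0.176) <= 3 * law.stderr_slope
    assert abs(law.intercept + 0.078) <= 3 * law.stderr_intercept


def test_crossing_law_scale_consistency():
    rng = np.random.default_rng(10)
    widths = rng.choice([0.4, 0.6, 0.8, 1.0], 200)
    sides = rng.choice([-1, 1], 200)
    x = sides * (0.176 * widths - 0.078) + rng.normal(0, 0.02, 200)
    law_m = agg.fit_crossing_model(widths, x, sides)
    law_cm = agg.fit_crossing_model(widths * 100, x * 100, sides)
    assert law_cm.slope == pytest.approx(law_m.slope, rel=1e-9)
    assert law_cm.intercept == pytest.approx(100 * law_m.intercept, rel=1e-9)


def test_crossing_law_single_width_rejected():
    with pytest.raises(ValueError):
        agg.fit_crossing_model(np.full(10, 0.5), np.zeros(10), np.ones(10))


# ------------------------------------------------------------ correlations

def _run_table(rng, n, couple=False):
    R = rng.uniform(0.8, 2.6, n)
    direction = rng.choice(["left", "right"], n)
    foot = np.where(direction == "left", "right", "left") if couple \
        else rng.choice(["left", "right"], n)
    return pd.DataFrame({
        "ratio_R": R,
        "max_amplitude": rng.normal(15, 5, n),
        "direction": direction,
        "width_w": rng.choice([0.4, 0.6, 0.8, 1.0], n),
        "foot_at_max": foot,
        "onset_d": rng.normal(0.5, 0.1, n),
    })


def test_correlation_self_is_shown():
    rng = np.random.default_rng(4)
    mats = agg.correlation_matrix(_run_table(rng, 300))
    for mat in mats.values():
        np.testing.assert_allclose(np.diag(mat), 1.0)


def test_correlation_type_I_mask_rate():
    """Independent variables: at least ~93% of off-diagonal entries masked
    at a nominal 95% level."""
    rng = np.random.default_rng(5)
    masked, total = 0, 0
    for rep in range(12):
        mats = agg.correlation_matrix(_run_table(rng, 500))
        for mat in mats.values():
            off = mat.to_numpy()[~np.eye(len(mat), dtype=bool)]
            total += len(off)
            masked += int(np.isnan(off).sum())
    assert masked / total >= 0.93


def test_correlation_deterministic_coupling_is_one():
    rng = np.random.default_rng(6)
    mats = agg.correlation_matrix(_run_table(rng, 400, couple=True))
    low = mats["R<=1.3"]
    assert abs(low.loc["direction", "foot_at_max"]) == pytest.approx(1.0)
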