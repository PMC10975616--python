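"""Per-run orchestration and experiment-level aggregation.

``analyze_run`` composes the measurement chain (crossing -> path distance ->
speed -> deceleration -> rotation -> steps) into one :class:`RunResult`.  It
never raises on per-run degeneracy: metrics that cannot be computed are left
``None`` with a reason code in ``RunResult.reasons``.

``analyze_experiment`` runs a collection of recordings and builds the
cross-run tables: the per-run result table, deceleration histogram, mean
speed/rotation profiles, exponential amplitude fits with R_crit per group,
the crossing-offset law and the significance-masked correlation matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import deceleration as dec
from . import kinematics as kin
from . import rotation as rot
from . import steps as stp
from .aggregate import (correlation_matrix, critical_point, fit_crossing_model,
                        fit_max_rotation_curve)
from .config import AnalysisConfig
from .trajectory_model import RunRecording


@dataclass
class RunResult:
    run_id: str
    participant: str
    angle_deg: float
    width_w: float
    length: float
    motivation: str
    ratio_R: float
    x_cross: float | None = None
    t_cross: float | None = None
    mean_speed: float | None = None
    vmax: float | None = None
    d_at_vmax: float | None = None
    vmin: float | None = None
    decel_category: str | None = None
    decel_point_d: float | None = None
    onset_d: float | None = None
    onset_t: float | None = None
    max_amplitude: float | None = None
    max_d: float | None = None
    max_t: float | None = None
    direction: str | None = None
    sigma_straight: float | None = None
    foot_at_onset: str = "none"
    foot_at_max: str = "none"
    footedness: str = "right"
    reasons: dict[str, str] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = asdict(self)
        row["reasons"] = ";".join(f"{k}:{v}" for k, v in self.reasons.items())
        return row


def analyze_run(rec: RunRecording, config: AnalysisConfig | None = None,
                *, keep_signals: bool = False) -> RunResult:
    """Run the full per-run measurement chain; degeneracies become reason codes."""
    cfg = config or AnalysisConfig()
    meta = rec.meta
    res = RunResult(run_id=meta.run_id, participant=meta.participant.id,
                    angle_deg=meta.angle_deg, width_w=meta.width_w,
                    length=meta.length, motivation=meta.motivation,
                    ratio_R=meta.ratio_R,
                    footedness=meta.participant.footedness)
    signals: dict[str, np.ndarray] = {}

    try:
        crossing = kin.compute_crossing(rec.com, max_abs_y=cfg.crossing_max_abs_y)
    except ValueError as e:
        res.reasons["crossing"] = str(e)
        return res
    res.x_cross = crossing.x_cross
    res.t_cross = crossing.t_cross

    d = kin.distance_to_crossing(rec.com, crossing)
    times = rec.times
    v = kin.speed_along_path(d, times, cfg.speed_window_s)
    signals.update(d=d, v=v, times=times)

    try:
        res.mean_speed = kin.mean_speed(rec.com, crossing, cfg.mean_speed_radius_m)
    except ValueError as e:
        res.reasons["mean_speed"] = str(e)
    try:
        vmax, d_at, _t_at, vmin = kin.find_vmax_vmin(v, d, times, cfg.vmax_window_m)
        res.vmax, res.d_at_vmax, res.vmin = vmax, d_at, vmin
    except ValueError as e:
        res.reasons["vmax"] = str(e)

    try:
        a = dec.smooth_acceleration(v, times, cfg.speed_window_s)
        signals["a"] = a
        groups = dec.group_negative(a, times, d, cfg.decel_window_m)
        thresholds = dec.DecelThresholds(
            duration_threshold_s=cfg.decel_duration_threshold_s,
            amplitude_threshold=cfg.decel_amplitude_threshold,
            window_m=cfg.decel_window_m,
            magnitude_comparison=cfg.decel_amplitude_magnitude)
        decel = dec.classify_deceleration(groups, a, times, d, thresholds)
        res.decel_category = decel.category
        res.decel_point_d = decel.decel_point_d
    except ValueError as e:
        res.reasons["deceleration"] = str(e)

    gamma = rot.shoulder_rotation(rec.shoulder_left, rec.shoulder_right,
                                  rec.com, cfg.rotation_window_s,
                                  cfg.min_com_displacement_m)
    signals["gamma"] = gamma
    events = None
    try:
        events = rot.rotation_onset(gamma, d, times, cfg.straight_window_m,
                                    cfg.onset_sigma_factor,
                                    cfg.onset_search_max_d,
                                    cfg.min_straight_samples,
                                    cfg.onset_center_straight)
    except ValueError as e:
        res.reasons["rotation"] = str(e)
    if events is None and "rotation" not in res.reasons:
        res.reasons["rotation"] = "no onset"
    events = rot.max_rotation(gamma, d, times, events)
    if events is not None:
        res.onset_d = events.onset_d
        res.onset_t = events.onset_t
        res.max_amplitude = events.max_amplitude
        res.max_d = events.max_d
        res.max_t = events.max_t
        res.sigma_straight = events.sigma_straight
        res.direction = "left" if events.max_amplitude >= 0 else "right"

    try:
        steps = stp.detect_heel_strikes(
            rec.heel_left, rec.heel_right, cfg.heel_threshold,
            threshold_rel=cfg.heel_threshold_rel,
            min_stance_s=cfg.min_stance_s,
            smooth_s=cfg.heel_speed_smooth_s, norm=cfg.heel_speed_norm)
        if events is not None:
            res.foot_at_onset = stp.foot_on_floor(steps, events.onset_t)
            res.foot_at_max = stp.foot_on_floor(steps, events.max_t)
    except ValueError as e:
        res.reasons["steps"] = str(e)

    if keep_signals:
        res.__dict__["signals"] = signals
    return res


def analyze_experiment(recordings, config: AnalysisConfig | None = None,
                       *, min_fit_points: int = 8) -> dict:
    """Analyze a collection of recordings and aggregate across runs.

    Returns a dict of tables: ``runs`` (per-run results), ``decel_histogram``,
    ``speed_profiles`` and ``rotation_profiles`` (two-stage bin means per
    angle/motivation), ``rotation_fits`` (exponential law + R_crit per
    (angle, motivation) where enough onsets exist), ``crossing_laws`` (per
    motivation) and ``correlations`` (masked matrices per R split).
    Deterministic given the input order.
    """
    cfg = config or AnalysisConfig()
    results: list[RunResult] = []
    speed_profiles: dict[tuple, list[kin.ProfileBins]] = {}
    rot_profiles: dict[tuple, list[kin.ProfileBins]] = {}
    for rec in recordings:
        res = analyze_run(rec, cfg, keep_signals=True)
        sig = res.__dict__.pop("signals", None)
        results.append(res)
        if sig and "v" in sig:
            key = (res.angle_deg, res.motivation)
            speed_profiles.setdefault(key, []).append(
                kin.bin_profile(sig["v"], sig["d"], cfg.profile_bin_m,
                                cfg.profile_range_m))
            rot_profiles.setdefault(key, []).append(
                kin.bin_profile(np.abs(sig["gamma"]), sig["d"],
                                cfg.profile_bin_m, cfg.profile_range_m))
    if not results:
        raise ValueError("empty collection")

    runs = pd.DataFrame([r.to_row() for r in results])

    out: dict = {"runs": runs}
    with_cat = runs.dropna(subset=["decel_category"])
    out["decel_histogram"] = (dec.deceleration_histogram(with_cat)
                              if len(with_cat) else pd.DataFrame())

    def profile_table(profiles: dict) -> pd.DataFrame:
        rows = []
        for (angle, motivation), plist in sorted(profiles.items()):
            mp = kin.mean_profile(plist)
            for c, m, n in zip(mp.centers, mp.means, mp.counts):
                rows.append({"angle_deg": angle, "motivation": motivation,
                             "d_bin_center": c, "mean": m, "n_runs": n})
        return pd.DataFrame(rows)

    out["speed_profiles"] = profile_table(speed_profiles)
    out["rotation_profiles"] = profile_table(rot_profiles)

    # exponential amplitude law and R_crit per (angle, motivation)
    fit_rows = []
    lo, hi, n_grid = cfg.rcrit_grid
    n_int = int(round((hi - lo) / cfg.rcrit_interval))
    with_max = runs.dropna(subset=["max_amplitude"])
    for (angle, motivation), sub in with_max.groupby(["angle_deg", "motivation"]):
        if len(sub) < min_fit_points:
            continue
        R = sub["ratio_R"].to_numpy()
        amp = np.abs(sub["max_amplitude"].to_numpy())
        try:
            fit = fit_max_rotation_curve(R, amp, r_domain=(lo, hi))
        except (ValueError, RuntimeError):
            continue
        counts = np.histogram(np.clip(R, lo, hi - 1e-9),
                              bins=n_int, range=(lo, hi))[0]
        row = {"angle_deg": angle, "motivation": motivation, "n": len(sub),
               "a": fit.a, "b": fit.b, "d": fit.d,
               "residual_sd": fit.residual_sd, "degenerate": fit.degenerate,
               "rcrit": np.nan}
        try:
            cp = critical_point(fit, fit.residual_sd, counts,
                                grid=cfg.rcrit_grid,
                                interval=cfg.rcrit_interval,
                                level=cfg.significance_level)
            row["rcrit"] = cp.rcrit
        except ValueError:
            pass
        fit_rows.append(row)
    out["rotation_fits"] = pd.DataFrame(fit_rows)

    # crossing-offset law per motivation
    law_rows = []
    with_x = runs.dropna(subset=["x_cross"])
    for motivation, sub in with_x.groupby("motivation"):
        if cfg.crossing_side_from == "angle":
            sides = np.sign(sub["angle_deg"].to_numpy())
        else:
            sides = np.sign(sub["x_cross"].to_numpy())
        try:
            law = fit_crossing_model(sub["width_w"].to_numpy(),
                                     sub["x_cross"].to_numpy(), sides)
        except ValueError:
            continue
        law_rows.append({"motivation": motivation, "slope": law.slope,
                         "intercept": law.intercept,
                         "stderr_slope": law.stderr_slope,
                         "shift_per_10cm_cm": law.shift_per_10cm_cm,
                         "n": law.n})
    out["crossing_laws"] = pd.DataFrame(law_rows)

    corr_vars = ["max_amplitude", "direction", "width_w", "motivation",
                 "angle_deg", "onset_d", "max_d", "foot_at_onset",
                 "foot_at_max", "footedness"]
    corr_input = runs.copy()
    corr_input["max_amplitude"] = corr_input["max_amplitude"].abs()
    corr_input[["foot_at_onset", "foot_at_max"]] = \
        corr_input[["foot_at_onset", "foot_at_max"]].replace("none", np.nan)
    try:
        out["correlations"] = correlation_matrix(
            corr_input, corr_vars, level=cfg.significance_level,
            r_split=cfg.r_split, method=cfg.correlation_method)
    except ValueError as e:
        out["correlations"] = {"error": str(e)}
    return out
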