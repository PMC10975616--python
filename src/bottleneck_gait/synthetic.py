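"""Synthetic bottleneck-run generator with a ground-truth channel.

Each generated run emulates one individual crossing the bottleneck:

* the COM follows a circular arc from the starting area (4 m radius at the
  approach angle) that blends tangentially into a straight exit segment
  through the crossing point, which is itself drawn from the linear
  crossing-offset law C(w);
* the speed profile is rest -> constant acceleration -> cruise (with a small
  positive drift and optional white noise) -> a deceleration feature drawn
  from the five braking categories -> exit;
* the shoulder line oscillates with the gait (counter-clockwise during a left
  foot swing), carries a turn-related rotation pulse that starts a fixed lead
  time before crossing and peaks shortly after it, and is perturbed by
  band-limited orientation noise;
* heels alternate stance and swing phases, the first step is always taken
  with the right foot, and the rotation direction is coupled to the stance
  foot (left turn <-> right foot on the floor) with configurable probability.

Every run returns a :class:`GroundTruth` record so each downstream detector
can be tested by parameter recovery without external data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory_model import (
    ANGLES_DEG, LENGTHS_M, MOTIVATIONS, WIDTHS_M,
    Participant, PointSeries, RunMeta, RunRecording,
)

DECEL_CATEGORIES = ("long_strong", "short_strong", "long_weak", "none",
                    "none_at_all")


# --------------------------------------------------------------- parameters

@dataclass
class SpeedParams:
    """Speed-profile parameters for one motivation condition.

    Defaults give cruise speeds of a0*T = 1.5 m/s (normal: 1.25 m/s^2 for
    1.2 s) and 2.1 m/s (hurried: 1.4 m/s^2 for 1.5 s).
    """

    a0: float
    T: float
    cruise_noise_sd: float = 0.05
    baseline_accel: float = 0.004  # m/s^2 drift during cruise; keeps the
                                   # noiseless acceleration strictly positive
                                   # outside deliberate braking features

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError("acceleration duration T must be > 0")
        if not self.a0 > 0:
            raise ValueError("a0 must be > 0")
        if self.cruise_noise_sd < 0:
            raise ValueError("cruise_noise_sd must be >= 0")

    @property
    def cruise_speed(self) -> float:
        return self.a0 * self.T


@dataclass
class DecelFeatureParams:
    """Shapes of the five braking categories, with margins against the
    classifier thresholds built in (the 0.5 s smoothing smears a sustained
    feature by about one window on each side).

    A feature may only start ``smooth_gap_s`` after cruise onset, so the
    smoothing window cannot mix the acceleration tail into the braking
    signal.  'Long' categories need enough runway for more than one second of
    in-window braking; when the remaining pre-crossing distance cannot
    support the drawn category, the generator falls back deterministically
    (long & strong -> short & strong, long & weak -> none, and to 'none at
    all' when even a short dip does not fit)."""

    strong_amp_range: tuple[float, float] = (0.3, 0.5)   # m/s^2
    weak_amp: float = 0.005          # sustained weak braking (< threshold)
    weak_dip_amp: float = 0.012      # brief weak dip; smoothing keeps the
                                     # smoothed peak well under the threshold
    long_duration_s: float = 1.2
    dip_duration_s: float = 0.5
    weak_long_duration_s: float = 2.0
    start_d_range: tuple[float, float] = (2.0, 2.4)      # m before crossing
    long_start_d_max: float = 3.3
    smooth_gap_s: float = 0.6        # cruise time before a strong feature
    weak_gap_s: float = 0.8          # weak features need more separation from
                                     # the smeared acceleration tail
    long_feasibility_time_s: float = 1.4


@dataclass
class RotationParams:
    """Shoulder-rotation generation for one motivation condition."""

    gait_amplitude_deg: float = 4.0
    cadence_steps_per_s: float = 1.9
    onset_lead_s: float = 0.41          # turn pulse starts this long before crossing
    peak_delay_s: float = 0.075         # pulse peak this long after crossing
    ramp_slope_deg_s: float | None = None  # fixed slope; None -> from amplitude law
    amp_a: float = 100.0                # |gamma_max|(R) = amp_a e^(-amp_b R) + amp_d
    amp_b: float = 2.0
    amp_d: float = 8.0
    amp_noise_sd: float = 2.0
    p_couple: float = 0.8               # P(left turn <-> right stance foot)
    orientation_noise_sd_deg: float = 1.0
    orientation_noise_tau_s: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_couple <= 1.0:
            raise ValueError("p_couple must be in [0, 1]")
        for name in ("amp_noise_sd", "orientation_noise_sd_deg",
                     "gait_amplitude_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def amplitude(self, R: float) -> float:
        return self.amp_a * np.exp(-self.amp_b * R) + self.amp_d


@dataclass
class CrossingLawParams:
    slope: float = 0.176      # m per m of width
    intercept: float = -0.078  # m
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_decel_mixture(angle_deg: float, motivation: str) -> np.ndarray:
    """Category probabilities per (angle, motivation): heavy braking clusters
    towards large approach angles and the hurried condition."""
    a = abs(angle_deg) / 90.0
    if motivation == "hurried":
        p = [0.32 + 0.10 * a, 0.32 + 0.10 * a, 0.02,
             0.17 - 0.10 * a, 0.17 - 0.10 * a]
    else:
        p = [0.20 + 0.10 * a, 0.20 + 0.10 * a, 0.16,
             0.22 - 0.10 * a, 0.22 - 0.10 * a]
    return np.asarray(p)


@dataclass
class SyntheticConfig:
    angles: tuple = ANGLES_DEG
    widths: tuple = WIDTHS_M
    lengths: tuple = LENGTHS_M
    motivations: tuple = MOTIVATIONS
    n_per_cell: int = 1
    seed: int = 0
    n_participants: int = 13
    population_mean_s: float = 0.43     # m (shoulder width)
    population_sd_s: float = 0.033      # m
    speed_params: dict = field(default_factory=lambda: {
        "normal": SpeedParams(a0=1.25, T=1.2),
        "hurried": SpeedParams(a0=1.4, T=1.5),
    })
    decel_mixture: dict | None = None   # {(angle, motivation): 5 probs}
    decel_features: DecelFeatureParams = field(default_factory=DecelFeatureParams)
    rotation_params: dict = field(default_factory=lambda: {
        "normal": RotationParams(onset_lead_s=0.41, peak_delay_s=0.075),
        "hurried": RotationParams(onset_lead_s=0.46, peak_delay_s=0.02),
    })
    crossing_law: CrossingLawParams = field(default_factory=CrossingLawParams)
    position_noise_sd: float = 0.005    # m, band-limited (AR(1))
    position_noise_tau_s: float = 0.2
    start_radius: float = 4.0
    blend_y: float = 1.0                # m; arc blends into the exit line here
    exit_length: float = 4.0
    stand_duration_s: float = 0.4
    sample_rate: float = 60.0
    step_duty: float = 0.6              # stance fraction of the two-step cycle
    lateral_heel_offset: float = 0.10
    infeasible: str = "resample"        # or "error"

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if self.position_noise_sd < 0 or self.population_sd_s < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.decel_mixture is not None:
            for key, p in self.decel_mixture.items():
                p = np.asarray(p, dtype=float)
                if len(p) != 5 or not np.isclose(p.sum(), 1.0):
                    raise ValueError(
                        f"decel mixture for {key} must be 5 probabilities summing to 1")
                if np.any(p < 0):
                    raise ValueError(f"decel mixture for {key} has negative entries")

    def mixture(self, angle: float, motivation: str) -> np.ndarray:
        if self.decel_mixture is not None:
            key = (angle, motivation)
            if key in self.decel_mixture:
                return np.asarray(self.decel_mixture[key], dtype=float)
        return default_decel_mixture(angle, motivation)


# --------------------------------------------------------------- ground truth

@dataclass
class GroundTruth:
    run_id: str
    side: int                      # +1 approach from positive angles' side
    x_cross: float                 # m, drawn from the crossing law
    t_cross: float                 # s
    cruise_speed: float
    decel_category: str
    decel_point_d: float | None
    direction: str                 # 'left' / 'right' turn
    onset_d: float
    onset_t: float
    max_amplitude: float           # deg, signed (+ left)
    max_d: float
    max_t: float
    strike_times: np.ndarray
    strike_labels: list[str]
    foot_at_onset: str
    foot_at_max: str
    coupled: bool
    gamma_true: np.ndarray | None = None   # generated rotation signal (deg)


def ground_truth_table(gts: list[GroundTruth]) -> pd.DataFrame:
    """Flat per-run ground-truth table (strike trains summarised by count)."""
    rows = []
    for g in gts:
        rows.append({
            "run_id": g.run_id, "side": g.side, "x_cross": g.x_cross,
            "t_cross": g.t_cross, "cruise_speed": g.cruise_speed,
            "decel_category": g.decel_category, "decel_point_d": g.decel_point_d,
            "direction": g.direction, "onset_d": g.onset_d, "onset_t": g.onset_t,
            "max_amplitude": g.max_amplitude, "max_d": g.max_d, "max_t": g.max_t,
            "n_strikes": len(g.strike_times),
            "first_strike_label": g.strike_labels[0] if g.strike_labels else "",
            "foot_at_onset": g.foot_at_onset, "foot_at_max": g.foot_at_max,
            "coupled": g.coupled,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------- path geometry

class _PathGeometry:
    """Arc-to-line blend from the starting area to the exit.

    A circular arc starts at the starting-area centre and meets the vertical
    exit line x = x_cross tangentially at y = blend_y; from there the path is
    straight through the crossing point down to the end of the exit segment.
    A straight approach (start directly above the crossing point) degenerates
    to a vertical line.  Positions are closed-form in arc length, so sampled
    chord lengths carry no interpolation jitter.
    """

    def __init__(self, start_xy: np.ndarray, x_cross: float, blend_y: float,
                 exit_length: float):
        self.x_cross = float(x_cross)
        self.blend_y = float(blend_y)
        self.exit_length = float(exit_length)
        dx = float(start_xy[0] - x_cross)
        dy = float(start_xy[1] - blend_y)
        self._straight = abs(dx) < 1e-9
        if self._straight:
            if dy <= 0:
                raise ValueError(
                    "straight approach requires the start above the blend point")
            self.arc_len = dy
        else:
            sign = 1.0 if dx > 0 else -1.0
            r = (dx * dx + dy * dy) / (2.0 * abs(dx))
            self._r = r
            self._sign = sign
            self._center = np.array([x_cross + sign * r, blend_y])
            phi_start = np.arctan2(start_xy[1] - self._center[1],
                                   start_xy[0] - self._center[0])
            phi_end = np.pi if sign > 0 else 0.0
            if sign > 0:     # counter-clockwise towards phi = pi
                dphi = (phi_end - phi_start) % (2 * np.pi)
            else:            # clockwise towards phi = 0
                dphi = (phi_start - phi_end) % (2 * np.pi)
            self._phi_start = phi_start
            self._dphi = dphi
            self.arc_len = r * dphi
        self.pre_length = self.arc_len + self.blend_y
        self.total_length = self.pre_length + self.exit_length

    def position(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        out = np.empty((len(s), 2))
        on_arc = s < self.arc_len
        sa = np.clip(s[on_arc], 0.0, self.arc_len)
        if self._straight:
            out[on_arc, 0] = self.x_cross
            out[on_arc, 1] = self.blend_y + (self.arc_len - sa)
        else:
            phi = self._phi_start + self._sign * sa / self._r
            out[on_arc, 0] = self._center[0] + self._r * np.cos(phi)
            out[on_arc, 1] = self._center[1] + self._r * np.sin(phi)
        rest = ~on_arc
        out[rest, 0] = self.x_cross
        out[rest, 1] = self.blend_y - (s[rest] - self.arc_len)
        return out

    def heading(self, s: np.ndarray) -> np.ndarray:
        """Tangent direction (radians) of travel at arc length ``s``."""
        s = np.asarray(s, dtype=float)
        out = np.full(len(s), -np.pi / 2.0)   # straight down (0, -1)
        on_arc = s < self.arc_len
        if not self._straight and np.any(on_arc):
            phi = self._phi_start + self._sign * s[on_arc] / self._r
            # velocity of CCW motion is (-sin, cos); CW is (sin, -cos)
            out[on_arc] = np.arctan2(self._sign * np.cos(phi),
                                     -self._sign * np.sin(phi))
        return out


# --------------------------------------------------------------- helpers

def _ar1_noise(rng: np.random.Generator, n: int, sd: float, tau: float,
               dt: float) -> np.ndarray:
    """Stationary AR(1) (discretised Ornstein-Uhlenbeck) noise."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    phi = np.exp(-dt / tau) if tau > 0 else 0.0
    x = np.empty(n)
    innov = rng.normal(0.0, 1.0, n)
    x[0] = innov[0]
    scale = np.sqrt(1.0 - phi * phi)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + scale * innov[i]
    return sd * x


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _time_to_cross(d0: float, v: float, decel: float) -> float:
    """Time to cover ``d0`` metres starting at speed ``v`` under constant
    deceleration ``decel`` (0 for none); inf if the walker stops first."""
    if decel <= 0:
        return d0 / v
    disc = v * v - 2.0 * decel * d0
    if disc <= 0:
        return np.inf
    return (v - np.sqrt(disc)) / decel


def _plan_decel(rng: np.random.Generator, category: str,
                feat: DecelFeatureParams, v_c: float,
                d_cruise_start: float) -> tuple[str, dict]:
    """Resolve the drawn category against the available runway and lay out the
    acceleration phases of the feature.  Returns (actual category, plan)."""
    t_need = feat.long_feasibility_time_s
    a_min = feat.strong_amp_range[0]
    limit_strong = d_cruise_start - feat.smooth_gap_s * v_c
    limit_weak = d_cruise_start - feat.weak_gap_s * v_c
    if category == "long_strong":
        d0 = min(feat.long_start_d_max, limit_strong)
        if _time_to_cross(d0, v_c, a_min) < t_need:
            category = "short_strong"
        else:
            return category, {
                "start_d": d0 - rng.uniform(0.0, 0.1), "gap": feat.smooth_gap_s,
                "phases": [(-rng.uniform(*feat.strong_amp_range),
                            feat.long_duration_s)]}
    if category == "long_weak":
        d0 = min(feat.long_start_d_max, limit_weak)
        if _time_to_cross(d0, v_c, 0.0) < t_need:
            category = "none"
        else:
            return category, {
                "start_d": d0 - rng.uniform(0.0, 0.1), "gap": feat.weak_gap_s,
                "phases": [(-feat.weak_amp, feat.weak_long_duration_s)]}
    half = feat.dip_duration_s / 2.0
    if category == "short_strong":
        d0 = min(rng.uniform(*feat.start_d_range), limit_strong - 0.05)
        if d0 >= v_c * half + 0.1:
            amp = rng.uniform(*feat.strong_amp_range)
            return category, {"start_d": d0, "gap": feat.smooth_gap_s,
                              "phases": [(-amp, half), (amp, half)]}
        category = "none_at_all"
    if category == "none":
        d0 = min(rng.uniform(*feat.start_d_range), limit_weak - 0.05)
        if d0 >= v_c * half + 0.1:
            return category, {"start_d": d0, "gap": feat.weak_gap_s,
                              "phases": [(-feat.weak_dip_amp, half),
                                         (feat.weak_dip_amp, half)]}
        category = "none_at_all"
    return "none_at_all", {"start_d": None, "gap": 0.0, "phases": []}


# --------------------------------------------------------------- generate_run

def generate_run(cfg: SyntheticConfig, meta: RunMeta,
                 seed) -> tuple[RunRecording, GroundTruth]:
    """Generate one run and its ground truth.

    ``seed`` may be an int or a sequence of ints (fed to
    ``numpy.random.default_rng``); within an experiment, run ``i`` uses
    ``[cfg.seed, i + 1]`` so single runs are reproducible in isolation.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / cfg.sample_rate
    speed = cfg.speed_params[meta.motivation]
    rot = cfg.rotation_params[meta.motivation]
    law = cfg.crossing_law
    feat = cfg.decel_features
    s_width = meta.participant.shoulder_width_s

    # crossing point from the linear offset law
    side = int(np.sign(meta.angle_deg)) or int(rng.choice([-1, 1]))
    x_cross = None
    for _ in range(200):
        cand = side * (law.slope * meta.width_w + law.intercept) \
            + rng.normal(0.0, law.noise_sd)
        if abs(cand) <= meta.width_w / 2.0:
            x_cross = cand
            break
        if cfg.infeasible == "error":
            raise ValueError(
                f"infeasible crossing offset {cand:.3f} m for width {meta.width_w} m")
    if x_cross is None:
        raise ValueError("could not draw a feasible crossing offset in 200 tries")

    theta = np.radians(meta.angle_deg)
    start = cfg.start_radius * np.array([np.sin(theta), np.cos(theta)])
    geom = _PathGeometry(start, x_cross, cfg.blend_y, cfg.exit_length)

    # braking category and feature plan (respecting the available runway)
    probs = cfg.mixture(meta.angle_deg, meta.motivation)
    drawn = str(rng.choice(DECEL_CATEGORIES, p=probs / probs.sum()))
    v_c = speed.cruise_speed
    d_cruise_start = geom.pre_length - v_c ** 2 / (2.0 * speed.a0)
    category, plan = _plan_decel(rng, drawn, feat, v_c, d_cruise_start)

    # ---- forward simulation of the speed profile -------------------------
    n_max = int((cfg.stand_duration_s + speed.T
                 + 3.0 * geom.total_length / max(v_c, 0.1)) / dt) + 200
    t_arr = np.zeros(n_max)
    v_arr = np.zeros(n_max)
    s_arr = np.zeros(n_max)
    v_state = 0.0
    s_state = 0.0
    phase = "stand"
    feature_t0 = None
    feature_done = False
    t_cruise_start = None
    decel_point_d = None
    i = 0
    while i < n_max - 1:
        t = i * dt
        d_now = geom.pre_length - s_state
        if phase == "stand" and t >= cfg.stand_duration_s:
            phase = "accel"
        if phase == "accel" and v_state >= v_c:
            v_state = v_c
            phase = "cruise"
            t_cruise_start = t
        if (phase == "cruise" and not feature_done
                and plan["start_d"] is not None
                and t >= t_cruise_start + plan["gap"]
                and d_now <= plan["start_d"]):
            phase = "feature"
            feature_t0 = t
            decel_point_d = d_now
        a = 0.0
        if phase == "accel":
            a = speed.a0
        elif phase == "cruise":
            a = speed.baseline_accel
        elif phase == "feature":
            trel = t - feature_t0
            acc = None
            edge = 0.0
            for amp, dur in plan["phases"]:
                if trel < edge + dur:
                    acc = amp
                    break
                edge += dur
            if acc is None:
                phase = "cruise"
                feature_done = True
                a = speed.baseline_accel
            else:
                a = acc
        noise = rng.normal(0.0, speed.cruise_noise_sd) \
            if phase in ("cruise", "feature") and speed.cruise_noise_sd > 0 else 0.0
        v_obs = max(v_state + noise, 0.0) if phase != "stand" else 0.0
        t_arr[i] = t
        v_arr[i] = v_obs
        s_arr[i] = s_state
        s_state += v_obs * dt
        v_state = max(v_state + a * dt, 0.0)
        i += 1
        if s_state >= geom.total_length:
            t_arr[i] = i * dt
            v_arr[i] = v_obs
            s_arr[i] = s_state
            i += 1
            break
    n = i
    t_arr, v_arr, s_arr = t_arr[:n], v_arr[:n], s_arr[:n]
    if s_arr[-1] < geom.total_length:
        raise RuntimeError("simulation did not reach the end of the path")

    t_cross = float(np.interp(geom.pre_length, s_arr, t_arr))
    com_clean = geom.position(s_arr)
    heading = geom.heading(s_arr)

    # ---- rotation signal --------------------------------------------------
    T_step = 1.0 / rot.cadence_steps_per_s
    t_go = cfg.stand_duration_s
    # the first (right-foot) touchdown lands once the body has picked up
    # speed, so the first swing is fast enough to register as a real step
    t_first = t_go + 1.9 * T_step

    R = meta.ratio_R
    if rot.ramp_slope_deg_s is not None:
        amp = rot.ramp_slope_deg_s * (rot.onset_lead_s + rot.peak_delay_s)
    else:
        amp = max(rot.amplitude(R) + rng.normal(0.0, rot.amp_noise_sd), 1.0)
    direction = "left" if side > 0 else "right"
    dir_sign = 1.0 if direction == "left" else -1.0

    t_on = t_cross - rot.onset_lead_s
    t_peak = t_cross + rot.peak_delay_s
    slope = amp / (t_peak - t_on)
    turn = np.where(t_arr < t_on, 0.0,
                    np.where(t_arr <= t_peak, slope * (t_arr - t_on),
                             np.maximum(amp - slope * (t_arr - t_peak), 0.0)))
    turn = dir_sign * turn

    # stance-foot coupling: adjust the gait phase so the foot on the floor at
    # the rotation maximum matches the left-turn <-> right-foot rule with
    # probability p_couple
    coupled = bool(rng.random() < rot.p_couple)
    desired = ("right" if direction == "left" else "left") if coupled \
        else ("left" if direction == "left" else "right")

    def foot_at(trains: np.ndarray, t: float) -> str:
        k = int(np.searchsorted(trains, t, side="right")) - 1
        if k < 0:
            return "none"
        return "right" if k % 2 == 0 else "left"

    t_end = t_arr[-1]

    def build_train(tf: float) -> np.ndarray:
        ks = np.arange(int(np.ceil((t_end - tf) / T_step)) + 1)
        train = tf + ks * T_step
        return train[train <= t_end]

    train = build_train(t_first)
    if foot_at(train, t_peak) != desired:
        # shift the strike train by half a step so the strike preceding the
        # rotation peak flips parity; direction chosen from the phase fraction
        frac = ((t_peak - t_first) / T_step) % 1.0
        t_first += T_step / 2.0 if frac < 0.5 else -T_step / 2.0
    # keep the rotation peak away from strike boundaries so detector timing
    # jitter (a sample or two) cannot flip the governing stance foot
    frac = ((t_peak - t_first) / T_step) % 1.0
    if frac < 0.15:
        t_first -= (0.15 - frac) * T_step
    elif frac > 0.85:
        t_first += (frac - 0.85) * T_step
    train = build_train(t_first)

    gait_phase = np.pi * (t_arr - t_first) / T_step
    ramp_in = _smoothstep((t_arr - t_go) / (2.0 * T_step))
    gait = rot.gait_amplitude_deg * np.sin(gait_phase) * ramp_in

    orient_noise = _ar1_noise(rng, n, rot.orientation_noise_sd_deg,
                              rot.orientation_noise_tau_s, dt)
    gamma_total = gait + turn + orient_noise

    facing = heading + np.radians(gamma_total)
    line_angle = facing + np.pi / 2.0       # direction right -> left shoulder
    line_u = np.column_stack([np.cos(line_angle), np.sin(line_angle)])
    sl_clean = com_clean + (s_width / 2.0) * line_u
    sr_clean = com_clean - (s_width / 2.0) * line_u

    # ---- heel trajectories ------------------------------------------------
    def ground_point(t: float, lateral_sign: float) -> np.ndarray:
        s_at = float(np.interp(t, t_arr, s_arr))
        h = geom.heading(np.array([s_at]))[0]
        nvec = np.array([np.cos(h + np.pi / 2.0), np.sin(h + np.pi / 2.0)])
        return geom.position(np.array([s_at]))[0] \
            + lateral_sign * cfg.lateral_heel_offset * nvec

    def heel_series(foot: str) -> np.ndarray:
        lateral = 1.0 if foot == "left" else -1.0
        own = train[0::2] if foot == "right" else train[1::2]
        knots = [(-np.inf, ground_point(0.0, lateral))]
        for tk in own:
            knots.append((tk, ground_point(tk, lateral)))
        pos = np.empty((n, 2))
        for j, (tk, pk) in enumerate(knots):
            hold_start = max(tk, 0.0) if np.isfinite(tk) else 0.0
            if j + 1 < len(knots):
                next_tk = knots[j + 1][0]
                hold_end = max(next_tk - 0.8 * T_step, hold_start)
                next_pk = knots[j + 1][1]
                in_hold = (t_arr >= hold_start) & (t_arr < hold_end)
                in_swing = (t_arr >= hold_end) & (t_arr < next_tk)
                pos[in_hold] = pk
                if np.any(in_swing):
                    u = (t_arr[in_swing] - hold_end) / max(next_tk - hold_end, dt)
                    w = _smoothstep(u)[:, None]
                    pos[in_swing] = (1.0 - w) * pk + w * next_pk
            else:
                pos[t_arr >= hold_start] = pk
        return pos

    hl_clean = heel_series("left")
    hr_clean = heel_series("right")

    # ---- measurement noise and assembly ----------------------------------
    def noisy(p: np.ndarray) -> np.ndarray:
        if cfg.position_noise_sd == 0:
            return p.copy()
        nx = _ar1_noise(rng, n, cfg.position_noise_sd, cfg.position_noise_tau_s, dt)
        ny = _ar1_noise(rng, n, cfg.position_noise_sd, cfg.position_noise_tau_s, dt)
        return p + np.column_stack([nx, ny])

    rec = RunRecording(
        meta=meta,
        com=PointSeries(times=t_arr, positions=noisy(com_clean)),
        shoulder_left=PointSeries(times=t_arr, positions=noisy(sl_clean)),
        shoulder_right=PointSeries(times=t_arr, positions=noisy(sr_clean)),
        heel_left=PointSeries(times=t_arr, positions=noisy(hl_clean)),
        heel_right=PointSeries(times=t_arr, positions=noisy(hr_clean)),
    )

    # ground-truth strike listing: both feet already on the floor at t = 0
    # (right listed first: it lifts first), then the alternating train
    strike_times = np.concatenate([[0.0, 0.0], train])
    strike_labels = ["right", "left"] + [
        "right" if k % 2 == 0 else "left" for k in range(len(train))]

    gt = GroundTruth(
        run_id=meta.run_id, side=side, x_cross=float(x_cross),
        t_cross=t_cross, cruise_speed=v_c,
        decel_category=category,
        decel_point_d=None if decel_point_d is None else float(decel_point_d),
        direction=direction,
        onset_d=float(geom.pre_length - np.interp(t_on, t_arr, s_arr)),
        onset_t=float(t_on),
        max_amplitude=float(dir_sign * amp),
        max_d=float(geom.pre_length - np.interp(t_peak, t_arr, s_arr)),
        max_t=float(t_peak),
        strike_times=strike_times, strike_labels=strike_labels,
        foot_at_onset=foot_at(train, t_on),
        foot_at_max=foot_at(train, t_peak),
        coupled=coupled,
        gamma_true=gamma_total,
    )
    return rec, gt


# ----------------------------------------------------------- experiment level

def make_population(cfg: SyntheticConfig) -> list[Participant]:
    """Draw the synthetic participant population (shoulder widths ~ N(mean, sd),
    footedness split evenly)."""
    rng = np.random.default_rng([cfg.seed, 0])
    widths = np.clip(rng.normal(cfg.population_mean_s, cfg.population_sd_s,
                                cfg.n_participants), 0.25, None)
    return [
        Participant(id=f"p{k + 1:02d}", shoulder_width_s=float(widths[k]),
                    footedness="right" if k % 2 == 0 else "left")
        for k in range(cfg.n_participants)
    ]


def enumerate_runs(cfg: SyntheticConfig) -> list[RunMeta]:
    """Full factorial run matrix: widths x lengths x motivations (the setups)
    x participants x angles x n_per_cell, in deterministic order."""
    if not (cfg.angles and cfg.widths and cfg.lengths and cfg.motivations):
        raise ValueError("empty design grid")
    participants = make_population(cfg)
    metas = []
    for width, length, motivation in itertools.product(
            cfg.widths, cfg.lengths, cfg.motivations):
        for part in participants:
            for angle in cfg.angles:
                for rep in range(cfg.n_per_cell):
                    rid = (f"{part.id}_a{angle:+04.0f}_w{width:.1f}"
                           f"_l{length:.1f}_{motivation}_r{rep}")
                    metas.append(RunMeta(participant=part, angle_deg=angle,
                                         width_w=width, length=length,
                                         motivation=motivation, run_id=rid))
    return metas


def n_setups(cfg: SyntheticConfig) -> int:
    return len(cfg.widths) * len(cfg.lengths) * len(cfg.motivations)


def generate_experiment(cfg: SyntheticConfig):
    """Yield ``(RunRecording, GroundTruth)`` for the full factorial design.

    Reproducible: run ``i`` is generated from seed ``[cfg.seed, i + 1]``, so
    the same config yields byte-identical output and any single run can be
    regenerated in isolation.
    """
    metas = enumerate_runs(cfg)
    for i, meta in enumerate(metas):
        yield generate_run(cfg, meta, [cfg.seed, i + 1])
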