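# Methods

This package implements the measurement chain used to analyse individual
pedestrians crossing a bottleneck from 3D motion-capture recordings (centre of
mass, both acromion shoulder points, both heels, nominally 60 Hz), plus a
synthetic gait generator that produces such recordings with a ground-truth
channel so every detector can be validated by parameter recovery.

## Coordinate conventions

Origin at the bottleneck centre; the crossing line is `y = 0`, approach side
`y > 0`, exit side `y < 0`. The approach angle is measured from the
straight-ahead axis (0° = straight), positive towards `+x`; starting areas lie
on a 4 m radius. Distances in metres, times in seconds, angles in degrees.
With this convention the crossing-offset law holds with a single sign rule:
positive angles (approach from `+x`) give offsets `0.176 w − 0.078`.

## Per-run measurements

**Crossing point.** The COM sample closest to `y = 0`, reported by its `x`
position (ties → earliest sample). Because ±90° starting areas sit *on* the
crossing line at `x = ±4 m`, the search is restricted to the final approach —
samples after the last one with `y > 0.5 m`. On paths that cross the line
once this equals the global argmin of `|y|`.

**Distance to crossing `d`.** Signed arc length along the COM path to the
crossing sample (chord sums; positive before, negative after). All phase
windows are defined on `d`: acceleration phase ends 3.5 m before crossing,
the straight-walking phase spans 3.5–1.5 m, the crossing phase ±1.5 m.

**Speed.** `v(t) = (d(t−h') − d(t+h'))/(2h')` with
`h' = min(0.25 s, t − t_first, t_last − t)` — the exact 0.5 s centred mean of
the instantaneous path speed, with a symmetrically shrinking window at the
trajectory edges (one-sided differences at the two boundary samples). The
0.5 s window is approximately one step, which suppresses the step-frequency
oscillation. `vmax` is searched in `d ∈ [0, 3.5]` m, `vmin` from the time of
`vmax` to the last sample. The per-run *mean speed* divides path length by
elapsed time from the first sample inside a 3 m radius of the origin (this
excludes the acceleration phase) to the crossing.

**Smoothed acceleration.** Central difference of `v` followed by the same
0.5 s shrinking-window running mean. Exact on affine speed signals. The
double smoothing smears a braking episode by roughly one window on each side;
the generator accounts for this (below).

**Braking categories.** Maximal runs of strictly negative smoothed
acceleration restricted to `d ∈ [0, 3.5]` m are rated against a duration
threshold of 1 s and an amplitude threshold of −0.0075 m/s² (three standard
deviations of straight-walking acceleration noise; also computable per run
from the straight window). The first group longer than 1 s is rated if one
exists, otherwise the first group: long & strong / short & strong / long &
weak / none, and "none at all" when the window holds no negative sample.
"Longer than 1 s" is read strictly; "larger than the threshold" as larger in
magnitude (`a ≤ −0.0075`; a literal signed reading is available per config).
Group duration counts one extra sample period so single samples have nonzero
duration. The deceleration point is the first sample of the rated group.

**Shoulder rotation γ.** The shoulder line runs from the right to the left
acromion; rotated clockwise by 90° it gives the facing direction. γ is the
signed angle from the movement direction — the COM chord across a 0.5 s
window, shrinking one-sidedly at the edges — to the facing direction;
positive = left turn. Samples where the COM moves < 1 mm across the window
are undefined and excluded downstream. The onset is the first sample past the
straight-walking window where |γ − straight mean| exceeds 3× the
straight-window standard deviation; subtracting the straight mean removes
per-run posture bias (flag to disable). The maximum is the largest
|excursion| after onset, reported signed with its location in `d` (negative =
after crossing); the onset search begins only after the straight window so
the baseline cannot contain its own trigger.

**Heel strikes.** Heel speed is `|vx| + |vy|` (central differences; Euclidean
norm per config), lightly smoothed (0.15 s running mean — raw differences of
millimetre position noise at 60 Hz would bury the stance band). Stance phases
are runs below a threshold (default: 20% of the 95th percentile of combined
heel speed) lasting ≥ 0.1 s; the strike is the stance start. Ties in strike
time (both feet standing at the first sample) order the foot whose stance
ends first ahead — the foot that moves first made contact first. The foot on
the floor at an event is the latest strike before it, or `none` before the
first strike or when the governing label repeats its predecessor (a missed
contact cannot be excluded).

## Aggregate statistics

**Profiles.** Per-run means in 0.1 m bins of `d` over [−1, 4] m, then an
unweighted mean per bin across runs (two-stage; never pooled).

**Crossing-offset law.** Offsets folded by side of origin (sign of the
angle; runs at 0° excluded by default) and regressed on width:
`C(w) = slope·w + intercept`. The reported shift per 10 cm of width is
`slope × 10` cm.

**Amplitude law and R_crit.** |γmax| against `R = w/s` is fitted to
`a·e^(−bR+c) + d`; `a` and `c` are jointly unidentifiable, so the equivalent
`a'·e^(−bR) + d` is fitted (multi-start over decay rates, `b > 0`) and
reported with `c = 0`. Flat data are flagged degenerate with `d` the mean.
The critical ratio evaluates the fit on 180 evenly spaced points over
[0.8, 2.6], partitions them into 0.05-wide intervals, and compares interval
means all-pairs with a Tukey–Kramer test whose error model is the fit's
residual sd with the observed per-interval data counts; R_crit is the lower
edge of the earliest interval from which on no pair differs at the 0.95
level. This interval/error-model construction is this package's normative
reading of an otherwise under-specified grid procedure. It is monotone in the
decay rate: steeper approaches to the plateau never increase R_crit.

**Tukey HSD.** All-pairs studentized-range comparisons (Tukey–Kramer for
unbalanced groups) via `scipy.stats.studentized_range`; the same code path
serves the sample-level tests and the R_crit grid.

**Correlations.** Pearson (Spearman per config) on ±1-encoded binary
variables; `none` feet drop out pairwise; entries with `p ≥ 0.05` are masked;
split at `R = 1.3` into "rotation expected" and "rotation not necessary"
regimes.

## Synthetic generator

Each run is built from five components:

* **Path**: a circular arc from the starting area that meets the vertical
  exit line tangentially 1 m before the crossing, then a straight segment
  through the crossing point to 4 m past it. The crossing point is drawn
  from the offset law `side·(0.176 w − 0.078)` plus Gaussian noise (sd
  0.05 m), redrawn if outside ±w/2. Positions are closed-form in arc length,
  so sampled chords carry no interpolation jitter.
* **Speed**: standing (0.4 s) → constant acceleration `a0` for `T` →
  cruise with white speed noise (sd 0.05 m/s) and a small positive drift
  (+0.004 m/s²) → a braking feature → exit. Defaults: (1.25 m/s², 1.2 s)
  normal and (1.4 m/s², 1.5 s) hurried, i.e. cruise speeds 1.5 and 2.1 m/s.
  The drift keeps the noiseless smoothed acceleration strictly positive
  outside deliberate features, so category recovery is not knife-edge against
  float-level jitter.
* **Braking feature**: drawn from a per-(angle, motivation) mixture over the
  five categories (heavy braking weighted towards large angles and the
  hurried condition). Long categories are sustained episodes (1.2 s strong at
  0.3–0.5 m/s²; 2 s weak at 0.005 m/s²); short categories are symmetric
  dips (0.5 s). Shapes are sized so the *smoothed* signal respects the
  classifier thresholds with margin, and features may only start a smoothing
  gap (0.6 s strong / 0.8 s weak) after cruise onset so the acceleration
  tail cannot blur into them. When the runway between cruise onset and the
  crossing cannot fit a category (fast near-straight runs), the generator
  falls back deterministically (long & strong → short & strong, long & weak →
  none, → none at all) and records the actual category in the ground truth.
  On noiseless runs the classifier recovers the generated category exactly.
* **Rotation**: shoulder orientation = path heading + gait oscillation +
  turn pulse + band-limited noise. The gait component (default 4° amplitude)
  is a sinusoid locked to the strike train, counter-clockwise during a left
  foot swing. The turn pulse rises linearly from a fixed lead time before
  crossing (0.41 s normal / 0.46 s hurried) to its peak shortly after
  crossing (0.075 s / 0.02 s) and decays symmetrically; its amplitude comes
  from the law `100·e^(−2R) + 8` degrees (or a fixed ramp slope per config).
  The default amplitude law has no angle dependence, so synthetic R_crit is
  flat across angles — a known difference from real crowds, where rotation
  demand grows with the turn. Orientation noise is an AR(1) process (sd 1°,
  0.2 s correlation time): postural sway is slow, not white.
* **Gait**: strikes alternate every `1/cadence` (default 1.9 steps/s)
  starting with the right foot; the first touchdown lands once the body has
  picked up speed so the first swing registers as a real step. Each foot
  holds its ground point (60% duty cycle) and swings smoothly (smoothstep) to
  the next; ground points sit 0.10 m lateral of the COM path. The strike
  phase is set so the foot on the floor at the rotation peak obeys the
  left-turn ↔ right-foot rule with probability `p_couple` (default 0.8), and
  the peak is kept away from strike boundaries so detector timing jitter
  cannot flip the governing foot.

Measurement noise is band-limited AR(1) position noise (sd 5 mm, 0.2 s
correlation time) added to every marker. Band-limited rather than white:
white 5 mm noise at 60 Hz would inflate chord-length speed estimates by ~12%
and bury heel-speed thresholds, neither of which happens with mocap-grade
recordings.

Randomness: one root seed; run *i* of an experiment uses
`default_rng([seed, i + 1])` and the participant population `[seed, 0]`, so
any single run is reproducible in isolation and experiments are byte-stable.

### What the generator does and does not emulate

It reproduces the statistical structure the detectors assume: the design
grid, the offset law, phase-structured speed profiles with categorised
braking, gait-locked shoulder oscillation with a turn pulse, alternating
stance with first-step-right, and stance/turn coupling. It does not attempt
biomechanically valid whole-body dynamics, angle-dependent rotation
amplitudes, hip/head rotation, speed-dependent shoulder–hip phasing, or
inter-person interaction. Passing recovery tests therefore demonstrates that
the measurement chain is correct and well-calibrated on signals with this
structure — not that the generator's defaults match any particular cohort.

## Recovery conditions (acceptance)

`bottleneck_gait.recovery` defines controlled conditions used by the
acceptance tests and `scripts/acceptance.py`: constant-approach-speed runs
with a 200°/s turn ramp and straight-phase rotation sd of 1° for the
onset/maximum detectors, and accelerate-then-cruise profiles for the vmax
medians. The 1° straight-phase sd is composed as 91% gait-locked periodic
variance plus 9% stochastic (AR(1), 0.1 s): a purely stochastic 1° signal
would trip the single-sample 3σ rule on roughly a quarter of runs before any
ramp, which real recordings do not show.

The sample-based onset rule has an irreducible detection lag: the ramp must
climb to 3σ (0.015 s at 200°/s) and detection lands on the next sample
(mean +0.008 s at 60 Hz), i.e. ≈ 0.03 m at 1.2 m/s and ≈ 0.04 m at
1.63 m/s. Mean detected onsets therefore sit slightly *below* lead-time ×
speed: ≈ 0.47 m for the normal condition and ≈ 0.71 m for the hurried one.

## Numerical choices and limitations

* Ties in every argmin/argmax → earliest sample.
* Profile bins with no samples propagate as NaN and drop out of cross-run
  means.
* Degenerate per-run metrics never raise inside `analyze_run`; they are
  reported as `None` with a reason code.
* The exponential fit reports curvature-based standard errors; for flat data
  it returns the degenerate plateau instead of an ill-posed fit.
* Problem sizes: the analysis drivers simulate 2184 runs (13 participants ×
  7 angles × 6 widths × 2 motivations × 2 repetitions, one bottleneck
  length); recovery conditions use 100–200 runs per condition, which puts
  standard errors comfortably below the tolerances being checked.
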