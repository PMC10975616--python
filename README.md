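# bottleneck-gait

Kinematic analysis of individual pedestrians crossing a bottleneck.

How a person uses a narrow passage — where they cross it, how they modulate
speed, whether and when they rotate their shoulders, and which foot is on the
floor while they do it — is a basic ingredient of pedestrian-dynamics models
and of safety-oriented facility design. This package implements the full
measurement chain for such experiments, taking per-run 3D motion-capture
recordings (centre of mass, shoulders, heels at 60 Hz) to per-run metrics and
cross-run statistics:

* **crossing point**: the COM sample closest to the bottleneck line `y = 0`,
  and the linear offset law `C(w) = ±0.176 w ∓ 0.078` (the crossing shifts
  1.76 cm towards the side of origin per 10 cm of bottleneck width);
* **speed along the path**: a 0.5 s centred running mean on the
  distance-to-crossing `d`, with `v_max` in the 3.5–0 m window and `v_min`
  after it;
* **braking behaviour**: five-way classification of negative-acceleration
  episodes (long/short × strong/weak, or none at all) against a 1 s duration
  and −0.0075 m/s² amplitude threshold;
* **shoulder rotation** `γ`: the signed angle between movement direction and
  facing (positive = left turn), with 3σ onset detection against the
  straight-walking baseline and the signed maximum after onset;
* **critical ratio** `R_crit`: the width-to-shoulder ratio `R = w/s` beyond
  which the maximum rotation stops changing, located from an exponential fit
  `a·e^(−bR) + d` by Tukey comparisons between 0.05-wide intervals of the
  fitted curve on [0.8, 2.6];
* **stance-foot coupling**: heel-strike detection from thresholded heel
  speed, foot-on-floor assignment at rotation events, and
  significance-masked correlation matrices split at `R = 1.3`.

A synthetic gait generator (`bottleneck_gait.synthetic`) produces full
recordings with the same statistical structure — arc-to-line approach paths,
phase-structured speed profiles with categorised braking, gait-locked
shoulder oscillation plus a turn pulse, alternating heel strikes starting
with the right foot — together with a ground-truth channel, so every detector
is testable by parameter recovery without access to laboratory data.

## Worked example

```python
from bottleneck_gait import analyze_run
from bottleneck_gait.synthetic import SyntheticConfig, generate_run, make_population
from bottleneck_gait.trajectory_model import RunMeta

cfg = SyntheticConfig(seed=1)
participant = make_population(cfg)[0]          # shoulder width 0.441 m
meta = RunMeta(participant=participant, angle_deg=60, width_w=0.5,
               length=1.0, motivation="normal", run_id="demo")
rec, truth = generate_run(cfg, meta, seed=8)
res = analyze_run(rec)
print(f"x_cross {res.x_cross:+.3f} m   vmax {res.vmax:.2f} m/s   "
      f"braking {res.decel_category}")
print(f"onset {res.onset_d:.2f} m before crossing, max {res.max_amplitude:+.1f} deg "
      f"at d = {res.max_d:+.2f} m, foot {res.foot_at_max}")
```

prints

```
x_cross -0.073 m   vmax 1.55 m/s   braking short_strong
onset 0.36 m before crossing, max +20.8 deg at d = -0.03 m, foot right
```

— the run crossed the 0.5 m bottleneck 7.3 cm off-centre (for widths close
to the shoulder width the turn direction dominates the crossing position),
braked in a short-and-strong dip, began rotating its shoulders 0.36 m before
the crossing line and reached its maximum left turn of ~21° just after
crossing, with the right foot on the floor (the left-turn ↔ right-foot
coupling).

The `analysis/` directory holds the full study pipeline as numbered drivers:
`01_simulate.py` (2184-run factorial experiment), `02_analyze_runs.py`
(per-run table), `03_aggregate.py` (offset law, amplitude fits and R_crit,
braking histogram, correlations) and `04_figures.py`. On the synthetic
defaults the recovered offset law prints `1.75 cm per 10 cm of width`
(hurried) against the configured 1.76, and median `vmax` 2.13 / 1.54 m/s for
hurried / normal walking.

There is also a small CLI: `bottleneck-gait simulate|analyze|aggregate|report`.

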