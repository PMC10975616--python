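import numpy as np
import pytest

from bottleneck_gait.synthetic import SyntheticConfig, generate_run, make_population
from bottleneck_gait.trajectory_model import (Participant, PointSeries, RunMeta,
                                              RunRecording)


@pytest.fixture(scope="session")
def participant():
    return Participant(id="p01", shoulder_width_s=0.43, footedness="right")


@pytest.fixture(scope="session")
def meta_factory(participant):
    def make(angle=0, width=0.8, length=1.0, motivation="normal", run_id="run"):
        return RunMeta(participant=participant, angle_deg=angle, width_w=width,
                       length=length, motivation=motivation, run_id=run_id)
    return make


@pytest.fixture(scope="session")
def clean_config():
    """Noiseless synthetic config (all stochastic amplitudes zero)."""
    def make(**kwargs):
        cfg = SyntheticConfig(seed=1, position_noise_sd=0.0, **kwargs)
        for sp in cfg.speed_params.values():
            sp.cruise_noise_sd = 0.0
        for rp in cfg.rotation_params.values():
            rp.orientation_noise_sd_deg = 0.0
            rp.amp_noise_sd = 0.0
        cfg.crossing_law.noise_sd = 0.0
        return cfg
    return make


@pytest.fixture(scope="session")
def synthetic_run(clean_config, meta_factory):
    """One deterministic noiseless run at +60 deg (arc path, rotation, steps)."""
    cfg = clean_config()
    rec, gt = generate_run(cfg, meta_factory(angle=60, width=0.6,
                                             run_id="fixture60"), 123)
    return rec, gt


def straight_recording(meta, speed=1.4, rate=60.0, y0=4.0, y1=-4.0,
                       x=0.0, gamma_deg=None):
    """Constant-speed straight-line recording, shoulders square to the path
    unless a rotation signal (deg, per sample) is given."""
    duration = (y0 - y1) / speed
    n = int(duration * rate) + 1
    t = np.arange(n) / rate
    y = y0 - speed * t
    com = np.column_stack([np.full(n, x), y])
    if gamma_deg is None:
        gam = np.zeros(n)
    elif callable(gamma_deg):
        gam = np.asarray(gamma_deg(t), dtype=float)
    else:
        gam = np.broadcast_to(np.asarray(gamma_deg, dtype=float), (n,)).copy()
    # walking towards -y: facing angle = -90 deg + gamma
    facing = np.radians(-90.0 + gam)
    line = facing + np.pi / 2.0
    u = np.column_stack([np.cos(line), np.sin(line)])
    s = meta.participant.shoulder_width_s
    heel = np.column_stack([np.full(n, x), y])
    return RunRecording(
        meta=meta,
        com=PointSeries(times=t, positions=com),
        shoulder_left=PointSeries(times=t, positions=com + u * s / 2),
        shoulder_right=PointSeries(times=t, positions=com - u * s / 2),
        heel_left=PointSeries(times=t, positions=heel + [0.1, 0.0]),
        heel_right=PointSeries(times=t, positions=heel - [0.1, 0.0]),
    )


@pytest.fixture(scope="session")
def straight_rec_factory(meta_factory):
    def make(**kwargs):
        meta = meta_factory(run_id=kwargs.pop("run_id", "straight"))
        return straight_recording(meta, **kwargs)
    return make
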