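"""Domain types, coordinate conventions and readers/writers for run recordings.

World frame
-----------
The origin sits at the bottleneck centre.  The crossing line is ``y = 0`` with
the approach side at ``y > 0`` and the exit side at ``y < 0``.  ``x > 0`` lies
on the side of positive approach angles; the approach angle is measured from
the straight-ahead axis (0 deg = straight approach), positive towards ``+x``.
Starting areas are centred on a 4 m radius around the origin.  Distances are
metres, times seconds, angles degrees.

File dialects
-------------
``long_csv`` is this package's canonical on-disk format: one row per
(body point, sample) with columns ``run_id, point_name, t, x, y[, z]`` and the
run metadata embedded in a ``# meta: {...}`` JSON header line.  ``petrack_txt``
reads the whitespace-separated tracker export (``id frame x y z`` per line,
configurable frame rate), mapping person ids to body points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: body-point names every recording must provide
BODY_POINTS = ("com", "shoulder_left", "shoulder_right", "heel_left", "heel_right")

#: the experiment's printed design grid
ANGLES_DEG = (-90, -60, -30, 0, 30, 60, 90)
WIDTHS_M = (0.4, 0.5, 0.6, 0.7, 0.8, 1.0)
LENGTHS_M = (0.2, 1.0, 2.0)
MOTIVATIONS = ("normal", "hurried")

_PLAUSIBLE_COORD_M = 50.0


@dataclass(frozen=True)
class Participant:
    """A study participant; ``shoulder_width_s`` is the ``s`` in R = w/s."""

    id: str
    shoulder_width_s: float
    footedness: str = "right"
    height: float | None = None

    def __post_init__(self) -> None:
        if not self.shoulder_width_s > 0:
            raise ValueError("shoulder_width_s must be > 0")
        if self.footedness not in ("right", "left"):
            raise ValueError("footedness must be 'right' or 'left'")


@dataclass(frozen=True)
class RunMeta:
    participant: Participant
    angle_deg: float
    width_w: float
    length: float
    motivation: str
    run_id: str

    def __post_init__(self) -> None:
        if not self.width_w > 0:
            raise ValueError("width_w must be > 0")
        if self.motivation not in MOTIVATIONS:
            raise ValueError(f"motivation must be one of {MOTIVATIONS}")

    @property
    def ratio_R(self) -> float:
        """Bottleneck width over shoulder width, R = w/s."""
        return self.width_w / self.participant.shoulder_width_s

    def in_printed_grid(self) -> bool:
        return (self.angle_deg in ANGLES_DEG and self.width_w in WIDTHS_M
                and self.length in LENGTHS_M)


@dataclass
class PointSeries:
    """Uniformly sampled planar (or 3D) positions of one body point."""

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("times must be 1-D with >= 2 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.positions.shape[0] != len(self.times):
            raise ValueError("positions/times length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def xy(self) -> np.ndarray:
        """Planar coordinates (first two columns)."""
        return self.positions[:, :2]

    def resampled(self, times: np.ndarray) -> "PointSeries":
        pos = np.column_stack([
            np.interp(times, self.times, self.positions[:, j])
            for j in range(self.positions.shape[1])
        ])
        return PointSeries(times=np.asarray(times, dtype=float), positions=pos)


@dataclass
class RunRecording:
    """One run: metadata plus the five body-point series on a shared time base."""

    meta: RunMeta
    com: PointSeries
    shoulder_left: PointSeries
    shoulder_right: PointSeries
    heel_left: PointSeries
    heel_right: PointSeries

    def series(self) -> dict[str, PointSeries]:
        return {name: getattr(self, name) for name in BODY_POINTS}

    @property
    def times(self) -> np.ndarray:
        return self.com.times


@dataclass(frozen=True)
class CrossingResult:
    x_cross: float
    t_cross: float
    index: int


def _common_grid(series: dict[str, PointSeries], rate_hz: float) -> np.ndarray:
    t0 = max(s.times[0] for s in series.values())
    t1 = min(s.times[-1] for s in series.values())
    if t1 <= t0:
        raise ValueError("series do not overlap in time")
    n = int(np.floor((t1 - t0) * rate_hz)) + 1
    return t0 + np.arange(n) / rate_hz


def _check_plausibility(series: dict[str, PointSeries]) -> None:
    for name, s in series.items():
        if np.any(np.abs(s.xy) > _PLAUSIBLE_COORD_M):
            raise ValueError(
                f"series {name!r} has coordinates beyond {_PLAUSIBLE_COORD_M} m; "
                "positions are expected in metres — check units")


def _assemble(meta: RunMeta, series: dict[str, PointSeries],
              rate_hz: float) -> RunRecording:
    missing = [p for p in BODY_POINTS if p not in series]
    if missing:
        raise ValueError(f"missing series: {', '.join(missing)}")
    _check_plausibility(series)
    grid = _common_grid(series, rate_hz)
    resampled = {k: v.resampled(grid) for k, v in series.items()}
    return RunRecording(meta=meta, **resampled)


def read_run_recording(path: str | Path, dialect: str = "long_csv", *,
                       meta: RunMeta | None = None,
                       frame_rate: float = 50.0,
                       point_map: dict[int, str] | None = None,
                       rate_hz: float = 60.0) -> RunRecording:
    """Read one run recording, resampled to a uniform ``rate_hz`` grid.

    ``long_csv`` embeds its metadata; for ``petrack_txt`` the tracker file has
    no metadata, so ``meta`` must be given and ``point_map`` maps person ids in
    the file to body-point names (default: ids 1..5 in ``BODY_POINTS`` order).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "long_csv":
        return _read_long_csv(path, meta=meta, rate_hz=rate_hz)
    if dialect == "petrack_txt":
        if meta is None:
            raise ValueError("petrack_txt carries no metadata; pass meta=")
        return _read_petrack(path, meta, frame_rate=frame_rate,
                             point_map=point_map, rate_hz=rate_hz)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _meta_to_dict(meta: RunMeta) -> dict:
    return {
        "run_id": meta.run_id, "angle_deg": meta.angle_deg,
        "width_w": meta.width_w, "length": meta.length,
        "motivation": meta.motivation,
        "participant": {
            "id": meta.participant.id,
            "shoulder_width_s": meta.participant.shoulder_width_s,
            "footedness": meta.participant.footedness,
            "height": meta.participant.height,
        },
    }


def _meta_from_dict(d: dict) -> RunMeta:
    p = d["participant"]
    return RunMeta(
        participant=Participant(id=p["id"],
                                shoulder_width_s=p["shoulder_width_s"],
                                footedness=p.get("footedness", "right"),
                                height=p.get("height")),
        angle_deg=d["angle_deg"], width_w=d["width_w"], length=d["length"],
        motivation=d["motivation"], run_id=d["run_id"])


def write_run_recording(rec: RunRecording, path: str | Path) -> Path:
    """Write a recording in the canonical long-CSV dialect (meta in header)."""
    path = Path(path)
    rows = []
    for name, s in rec.series().items():
        for i, t in enumerate(s.times):
            row = {"run_id": rec.meta.run_id, "point_name": name,
                   "t": t, "x": s.positions[i, 0], "y": s.positions[i, 1]}
            if s.positions.shape[1] > 2:
                row["z"] = s.positions[i, 2]
            rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write("# meta: " + json.dumps(_meta_to_dict(rec.meta)) + "\n")
        df.to_csv(fh, index=False, float_format="%.9g")
    return path


def _read_long_csv(path: Path, meta: RunMeta | None, rate_hz: float) -> RunRecording:
    header_meta = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# meta:"):
        header_meta = _meta_from_dict(json.loads(first[len("# meta:"):]))
    df = pd.read_csv(path, comment="#")
    required = {"run_id", "point_name", "t", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"long_csv requires columns {sorted(required)}")
    meta = meta or header_meta
    if meta is None:
        raise ValueError("no metadata: file has no '# meta:' header and meta= not given")
    series: dict[str, PointSeries] = {}
    cols = ["x", "y"] + (["z"] if "z" in df.columns else [])
    for name, sub in df.groupby("point_name"):
        sub = sub.sort_values("t")
        t = sub["t"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"non-monotonic times for series {name!r}")
        series[str(name)] = PointSeries(times=t, positions=sub[cols].to_numpy())
    return _assemble(meta, series, rate_hz)


def _read_petrack(path: Path, meta: RunMeta, frame_rate: float,
                  point_map: dict[int, str] | None, rate_hz: float) -> RunRecording:
    if point_map is None:
        point_map = {i + 1: name for i, name in enumerate(BODY_POINTS)}
    data = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            pid, frame = int(parts[0]), int(parts[1])
            coords = [float(v) for v in parts[2:5]]
            data.setdefault(pid, []).append((frame, *coords))
    series: dict[str, PointSeries] = {}
    for pid, rows in data.items():
        name = point_map.get(pid)
        if name is None:
            continue
        frames = np.array([r[0] for r in rows])
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"non-monotonic frames for person id {pid}")
        pos = np.array([r[1:] for r in rows], dtype=float)
        series[name] = PointSeries(times=frames / frame_rate, positions=pos)
    return _assemble(meta, series, rate_hz)


def write_results(results: pd.DataFrame, path: str | Path,
                  format: str = "csv") -> Path:
    """Write a per-run results table; round-trips at >= 6 significant digits."""
    if results is None or len(results) == 0:
        raise ValueError("refusing to write an empty results table")
    path = Path(path)
    if format == "csv":
        results.to_csv(path, index=False, float_format="%.9g")
    elif format == "json":
        results.to_json(path, orient="records", double_precision=10)
    else:
        raise ValueError(f"unknown format: {format!r}")
    return path


def read_results(path: str | Path, format: str = "csv") -> pd.DataFrame:
    path = Path(path)
    if format == "csv":
        return pd.read_csv(path)
    if format == "json":
        return pd.read_json(path, orient="records")
    raise ValueError(f"unknown format: {format!r}")


def mirror_run(rec: RunRecording) -> RunRecording:
    """Reflect a run about the x = 0 plane.

    Positions map x -> -x, the left/right shoulder and heel series swap roles,
    and the approach angle changes sign.  Applying it twice is the identity.
    """
    def flip(s: PointSeries) -> PointSeries:
        pos = s.positions.copy()
        pos[:, 0] = -pos[:, 0]
        return PointSeries(times=s.times.copy(), positions=pos)

    meta = replace(rec.meta, angle_deg=-rec.meta.angle_deg)
    return RunRecording(
        meta=meta,
        com=flip(rec.com),
        shoulder_left=flip(rec.shoulder_right),
        shoulder_right=flip(rec.shoulder_left),
        heel_left=flip(rec.heel_right),
        heel_right=flip(rec.heel_left),
    )
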