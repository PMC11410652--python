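"""Synthetic two-choice assay generator.

Produces ground-truth mosquito trajectories for a two-choice cage assay and
renders them to grayscale frames, so the whole tracking/scoring pipeline can
be exercised and validated without any recorded video.

Generative model
----------------
Each of ``n_mosquitoes`` is an independent renewal process alternating
flight and landed bouts.  Landing events arrive as a Poisson process whose
total rate is the sum of the two per-zone arrival rates; each landing picks
zone 1 or zone 2 with probability proportional to its rate, so a rate ratio
r2:r1 encodes a preference with expected seeking-observation share
r2/(r1+r2) in zone 2 and hence an expected preference index of
(r2-r1)/(r1+r2).  A landed bout lasts an exponential time and is either
stationary (fixed point plus sub-pixel centroid jitter) or seeking (an
upward-biased walk with log-normal speeds).  An optional activity schedule
multiplies the landing rate over given intervals, emulating CO2 pulses.

Rendering inverts the tracker's thresholding assumption: dark elliptical
blobs on a light background, flying mosquitoes smaller and fainter than
landed ones, plus i.i.d. Gaussian pixel noise.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from ._movement import UP, LogNormalSpeed, WrappedNormalHeading, walk_path
from .geometry import ArenaSpec, ZoneLayout
from .tracker import FrameStack

STATE_FLYING = "flying"
STATE_STATIONARY = "landed_stationary"
STATE_SEEKING = "landed_seeking"
STATES = (STATE_FLYING, STATE_STATIONARY, STATE_SEEKING)

#: Ground-truth / fixture CSV column order.
TRUTH_COLUMNS = ["frame", "time_s", "track_id", "x_px", "y_px", "area_px", "state"]

_META_NAME = "fixture.json"


@dataclass(frozen=True)
class ActivitySchedule:
    """Piecewise landing-rate multiplier, e.g. elevated activity after a CO2 pulse.

    ``intervals`` is a sequence of (start_s, end_s, multiplier); outside all
    intervals the multiplier is 1.
    """

    intervals: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        for s, e, m in self.intervals:
            if not (e > s and m >= 0 and math.isfinite(m)):
                raise ValueError("each interval needs end > start and a finite multiplier >= 0")

    def multiplier_at(self, t: float) -> float:
        for s, e, m in self.intervals:
            if s <= t < e:
                return m
        return 1.0

    @property
    def max_multiplier(self) -> float:
        return max([1.0] + [m for _, _, m in self.intervals])


@dataclass(frozen=True)
class BehaviorParams:
    """Behavioural parameters of the synthetic cohort.

    Rates are per mosquito per second.  The defaults emulate a cage of 80
    females with a mild overall activity level; preference is encoded purely
    in the ratio of the two arrival rates.
    """

    n_mosquitoes: int = 80
    arrival_rate_zone1: float = 0.01
    arrival_rate_zone2: float = 0.01
    bout_mean_s: float = 6.0
    stationary_fraction: float = 0.25
    walk_speed: LogNormalSpeed = field(default_factory=LogNormalSpeed)
    heading: WrappedNormalHeading = field(default_factory=WrappedNormalHeading)
    jitter_sd_px: float = 0.5
    landed_area_px2: tuple[float, float] = (80.0, 160.0)
    flying_area_px2: tuple[float, float] = (15.0, 35.0)
    flying_opacity: float = 0.4
    flight_speed: LogNormalSpeed = field(default_factory=lambda: LogNormalSpeed(250.0, 0.3))
    zones: Optional[ZoneLayout] = None
    activity_schedule: Optional[ActivitySchedule] = None

    def __post_init__(self) -> None:
        if self.n_mosquitoes < 0:
            raise ValueError("n_mosquitoes must be >= 0")
        for name in ("arrival_rate_zone1", "arrival_rate_zone2", "bout_mean_s", "jitter_sd_px"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and non-negative")
        if self.bout_mean_s <= 0:
            raise ValueError("bout_mean_s must be positive")
        if not 0 <= self.stationary_fraction <= 1:
            raise ValueError("stationary_fraction must lie in [0, 1]")
        if not 0 < self.flying_opacity <= 1:
            raise ValueError("flying_opacity must lie in (0, 1]")
        la, fa = self.landed_area_px2, self.flying_area_px2
        if not (0 < la[0] < la[1] and 0 < fa[0] < fa[1]):
            raise ValueError("area ranges must be increasing and positive")
        if not fa[1] < la[0]:
            raise ValueError("flying areas must lie strictly below landed areas")

    @property
    def total_arrival_rate(self) -> float:
        return self.arrival_rate_zone1 + self.arrival_rate_zone2


@dataclass
class GroundTruth:
    """Per-frame ground-truth observations of every synthetic mosquito.

    ``table`` columns: ``frame, time_s, track_id, x_px, y_px, area_px, state``
    plus ``mosquito_id``.  A track_id identifies one behavioural episode
    (one flight or one landed bout), so every track occupies contiguous
    frames, exactly like the fragments a tracker would recover.
    """

    arena: ArenaSpec
    table: pd.DataFrame

    def validate(self) -> None:
        t = self.table
        if len(t) == 0:
            return
        if not set(t["state"]).issubset(STATES):
            raise ValueError("unknown state label in ground truth")
        inside = ((t["x_px"] >= 0) & (t["x_px"] < self.arena.width_px)
                  & (t["y_px"] >= 0) & (t["y_px"] < self.arena.height_px))
        if not inside.all():
            raise ValueError("ground-truth positions outside the frame")
        for _, g in t.groupby("track_id"):
            f = np.sort(g["frame"].to_numpy())
            if not np.array_equal(f, np.arange(f[0], f[0] + len(f))):
                raise ValueError("track frames are not contiguous")

    def landed_table(self) -> pd.DataFrame:
        """Landed rows relabelled for the scoring layer (seeking/stationary)."""
        t = self.table[self.table["state"] != STATE_FLYING].copy()
        t["state"] = np.where(t["state"] == STATE_SEEKING, "seeking", "stationary")
        return t.reset_index(drop=True)


def _episode_frame_range(t0: float, t1: float, fps: float, n_frames: int) -> tuple[int, int]:
    f0 = int(np.ceil(t0 * fps - 1e-9))
    f1 = int(np.ceil(t1 * fps - 1e-9))
    return max(f0, 0), min(f1, n_frames)


def _next_landing_time(rng, t: float, rate: float,
                       schedule: Optional[ActivitySchedule], horizon: float) -> float:
    if rate <= 0:
        return math.inf
    if schedule is None:
        return t + rng.exponential(1.0 / rate)
    m = schedule.max_multiplier
    if m <= 0:
        return math.inf
    # thinning of an inhomogeneous Poisson process
    while t < horizon:
        t += rng.exponential(1.0 / (rate * m))
        if rng.random() < schedule.multiplier_at(t) / m:
            return t
    return math.inf


def simulate_ground_truth(arena: ArenaSpec, params: BehaviorParams, seed: int) -> GroundTruth:
    """Simulate the cohort and return per-frame ground truth.

    Reproducible given ``seed``; each mosquito consumes an independent
    sub-stream spawned from the master seed.
    """
    zones = params.zones or ZoneLayout.scaled(arena.height_px, arena.width_px)
    n_frames = arena.n_frames
    fps = arena.fps
    W, H = float(arena.width_px), float(arena.height_px)
    r1, r2 = params.arrival_rate_zone1, params.arrival_rate_zone2
    total = params.total_arrival_rate

    cols: dict[str, list] = {c: [] for c in
                             ("frame", "track_id", "mosquito_id", "x_px", "y_px", "area_px", "state")}
    next_track = 0

    def emit(f0, f1, track_id, mid, x, y, area, state):
        k = f1 - f0
        cols["frame"].append(np.arange(f0, f1))
        cols["track_id"].append(np.full(k, track_id))
        cols["mosquito_id"].append(np.full(k, mid))
        cols["x_px"].append(np.asarray(x, dtype=float))
        cols["y_px"].append(np.asarray(y, dtype=float))
        cols["area_px"].append(np.full(k, area))
        cols["state"].append(np.full(k, state, dtype=object))

    streams = np.random.SeedSequence(seed).spawn(params.n_mosquitoes)
    for mid, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        t = 0.0
        while t < arena.duration_s:
            # flight until the next landing (possibly past the end of the video)
            t_land = _next_landing_time(rng, t, total, params.activity_schedule, arena.duration_s)
            f0, f1 = _episode_frame_range(t, min(t_land, arena.duration_s), fps, n_frames)
            if f1 > f0:
                fx, fy = walk_path(rng, rng.uniform(0, W), rng.uniform(0, H), f1 - f0,
                                   arena.dt, params.flight_speed,
                                   WrappedNormalHeading(rng.uniform(-np.pi, np.pi), 2 * np.pi),
                                   W, H)
                area = int(round(rng.uniform(*params.flying_area_px2)))
                emit(f0, f1, next_track, mid, fx, fy, area, STATE_FLYING)
                next_track += 1
            if not math.isfinite(t_land) or t_land >= arena.duration_s:
                break
            # landed bout
            zone = zones.zone1 if rng.random() < (r1 / total) else zones.zone2
            dur = rng.exponential(params.bout_mean_s)
            t_end = min(t_land + dur, arena.duration_s)
            f0, f1 = _episode_frame_range(t_land, t_end, fps, n_frames)
            if f1 > f0:
                sx = rng.uniform(zone.x, zone.x + zone.w)
                sy = rng.uniform(zone.y, zone.y + zone.h)
                area = int(round(rng.uniform(*params.landed_area_px2)))
                if rng.random() < params.stationary_fraction:
                    jx = np.clip(sx + params.jitter_sd_px * rng.standard_normal(f1 - f0),
                                 0, W * (1 - 1e-9))
                    jy = np.clip(sy + params.jitter_sd_px * rng.standard_normal(f1 - f0),
                                 0, H * (1 - 1e-9))
                    emit(f0, f1, next_track, mid, jx, jy, area, STATE_STATIONARY)
                else:
                    wx, wy = walk_path(rng, sx, sy, f1 - f0, arena.dt,
                                       params.walk_speed, params.heading, W, H)
                    emit(f0, f1, next_track, mid, wx, wy, area, STATE_SEEKING)
                next_track += 1
            t = t_land + dur

    if not cols["frame"]:
        table = pd.DataFrame({
            "frame": pd.Series(dtype="int64"), "time_s": pd.Series(dtype="float64"),
            "track_id": pd.Series(dtype="int64"), "mosquito_id": pd.Series(dtype="int64"),
            "x_px": pd.Series(dtype="float64"), "y_px": pd.Series(dtype="float64"),
            "area_px": pd.Series(dtype="int64"), "state": pd.Series(dtype="object"),
        })
        return GroundTruth(arena, table)

    table = pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})
    table["frame"] = table["frame"].astype(np.int64)
    table["track_id"] = table["track_id"].astype(np.int64)
    table["mosquito_id"] = table["mosquito_id"].astype(np.int64)
    table["area_px"] = table["area_px"].astype(np.int64)
    table["time_s"] = table["frame"] / fps
    table = table[["frame", "time_s", "track_id", "mosquito_id",
                   "x_px", "y_px", "area_px", "state"]]
    return GroundTruth(arena, table.sort_values(["track_id", "frame"], ignore_index=True))


def _stamp_ellipse(canvas: np.ndarray, cx: float, cy: float, area: float,
                   angle: float, value: int, aspect: float = 2.0) -> None:
    a = math.sqrt(area * aspect / math.pi)
    b = a / aspect
    H, W = canvas.shape
    r = int(math.ceil(a)) + 1
    x0, x1 = max(0, int(cx) - r), min(W, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(H, int(cy) + r + 1)
    if x1 <= x0 or y1 <= y0:
        return
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    dx, dy = np.meshgrid(xs, ys)
    c, s = math.cos(angle), math.sin(angle)
    u = (dx * c + dy * s) / a
    v = (-dx * s + dy * c) / b
    m = u * u + v * v <= 1.0
    region = canvas[y0:y1, x0:x1]
    region[m] = np.minimum(region[m], value)


def render_frames(
    truth: GroundTruth,
    arena: ArenaSpec,
    render_seed: int = 0,
    *,
    background: int = 230,
    landed_intensity: int = 30,
    flying_opacity: float = 0.4,
    noise_sd: float = 3.0,
    aspect: float = 2.0,
) -> FrameStack:
    """Render ground truth to grayscale frames.

    Landed mosquitoes are opaque dark ellipses of the ground-truth pixel
    area; flying ones use their (smaller) ground-truth area and an intensity
    blended toward the background by ``flying_opacity``, so they threshold
    to smaller, fainter blobs.  i.i.d. Gaussian noise (default SD 3 grey
    levels) is added and clipped to [0, 255].
    """
    if (truth.arena.height_px, truth.arena.width_px) != (arena.height_px, arena.width_px):
        raise ValueError("ground truth and arena dimensions differ")
    t = truth.table
    if len(t) and (t["frame"].max() >= arena.n_frames):
        raise ValueError("ground truth extends past the arena frame budget")
    H, W, T = arena.height_px, arena.width_px, arena.n_frames
    rng = np.random.default_rng(render_seed)
    fly_value = int(round(background - flying_opacity * (background - landed_intensity)))

    # stable per-episode ellipse orientation
    track_ids = sorted(t["track_id"].unique()) if len(t) else []
    angles = {tid: rng.uniform(0, np.pi) for tid in track_ids}

    order = np.argsort(t["frame"].to_numpy(), kind="stable") if len(t) else np.empty(0, int)
    fr = t["frame"].to_numpy()[order] if len(t) else np.empty(0, int)
    xs = t["x_px"].to_numpy()[order] if len(t) else np.empty(0)
    ys = t["y_px"].to_numpy()[order] if len(t) else np.empty(0)
    areas = t["area_px"].to_numpy()[order] if len(t) else np.empty(0)
    tids = t["track_id"].to_numpy()[order] if len(t) else np.empty(0, int)
    flying = (t["state"].to_numpy()[order] == STATE_FLYING) if len(t) else np.empty(0, bool)
    bounds = np.searchsorted(fr, np.arange(T + 1))

    frames = np.empty((T, H, W), np.uint8)
    for f in range(T):
        canvas = np.full((H, W), background, np.uint8)
        for i in range(bounds[f], bounds[f + 1]):
            val = fly_value if flying[i] else landed_intensity
            _stamp_ellipse(canvas, xs[i], ys[i], areas[i], angles[tids[i]], val, aspect)
        if noise_sd > 0:
            noisy = canvas.astype(np.float32)
            noisy += noise_sd * rng.standard_normal((H, W), dtype=np.float32)
            canvas = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
        frames[f] = canvas
    return FrameStack(frames, arena.fps)


def write_fixture(truth: GroundTruth, frames: FrameStack, path, overwrite: bool = False) -> Path:
    """Write a fixture directory: PNG frame sequence, truth CSV and metadata."""
    p = Path(path)
    if p.exists() and not overwrite:
        raise FileExistsError(f"{p} already exists (pass overwrite=True)")
    p.mkdir(parents=True, exist_ok=True)
    for i in range(frames.n_frames):
        iio.imwrite(p / f"frame_{i:05d}.png", frames.frames[i])
    meta = {
        "fps": frames.fps, "height_px": frames.height, "width_px": frames.width,
        "n_frames": frames.n_frames, "duration_s": truth.arena.duration_s,
    }
    (p / _META_NAME).write_text(json.dumps(meta))
    truth.table[TRUTH_COLUMNS].to_csv(p / "truth.csv", index=False)
    return p


def read_fixture(path) -> tuple[GroundTruth, FrameStack]:
    """Read back a fixture written by :func:`write_fixture`."""
    p = Path(path)
    meta = json.loads((p / _META_NAME).read_text())
    stack = FrameStack.from_dir(p, fps=meta["fps"])
    arena = ArenaSpec(meta["height_px"], meta["width_px"], meta["fps"], meta["duration_s"])
    table = pd.read_csv(p / "truth.csv")
    return GroundTruth(arena, table), stack
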