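"""Random-walk power study for the minimum-HSI inclusion threshold.

Fictive mosquitoes walk on a 720 x 1280 mesh containing two 466 x 456
scoring zones.  Each walker starts at a uniformly random position and
alternates walking bouts and stationary pauses (both exponential); while
walking it takes per-frame steps with log-normal speed and wrapped-normal
heading centred on "up", with no left/right bias, reflecting at the frame
borders.  Scoring mirrors the real pipeline: every walking observation
inside a zone is a host-seeking observation, the PI is the normalised
between-zone difference and the HSI the per-frame mean number of walking
mosquitoes.  Because starts are uniform and the movement model is
left/right symmetric, the PI distribution is centred on zero; its spread
shrinks as the number of walkers (hence the HSI) grows, which is what sets
a principled minimum HSI for including an experiment.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from ._movement import LogNormalSpeed, WrappedNormalHeading
from .geometry import ArenaSpec, ZoneLayout

STUDY_COLUMNS = ["n", "iterations", "mean_pi", "sd_pi", "min_pi", "max_pi",
                 "mean_hsi", "undefined_count"]


@dataclass(frozen=True)
class WalkParams:
    """Movement model and arena of the fictive walkers."""

    arena: ArenaSpec = field(default_factory=ArenaSpec)
    zones: ZoneLayout = field(default_factory=ZoneLayout.default)
    speed: LogNormalSpeed = field(default_factory=LogNormalSpeed)
    heading: WrappedNormalHeading = field(default_factory=WrappedNormalHeading)
    walk_bout_mean_s: float = 5.0
    pause_mean_s: float = 5.0

    def __post_init__(self) -> None:
        if self.walk_bout_mean_s <= 0 or self.pause_mean_s < 0:
            raise ValueError("bout means must be positive (pause may be zero)")
        if (self.zones.frame_height, self.zones.frame_width) != \
                (self.arena.height_px, self.arena.width_px):
            raise ValueError("zone layout does not match the arena dimensions")


@dataclass
class WalkerPaths:
    """Vectorised walker trajectories: (n_walkers, n_frames) arrays."""

    x: np.ndarray
    y: np.ndarray
    walking: np.ndarray  # bool; True = in motion (seeking) at that frame
    fps: float

    @property
    def n_walkers(self) -> int:
        return self.x.shape[0]

    @property
    def n_frames(self) -> int:
        return self.x.shape[1]


class _Workspace:
    """Preallocated buffers reused across simulation chunks.

    Fresh multi-hundred-MB temporaries per chunk cost more in page faults
    than the arithmetic itself, so all large intermediates live here.
    """

    def __init__(self, rows: int, n_frames: int):
        self.rows = rows
        self.step_a = np.empty((rows, n_frames - 1), dtype=np.float32)
        self.step_b = np.empty((rows, n_frames - 1), dtype=np.float32)
        self.x = np.empty((rows, n_frames), dtype=np.float32)
        self.y = np.empty((rows, n_frames), dtype=np.float32)
        self.scratch = np.empty((rows, n_frames), dtype=np.float32)
        self.walking = np.empty((rows, n_frames), dtype=bool)
        self.mask = np.empty((rows, n_frames), dtype=bool)
        self.mask2 = np.empty((rows, n_frames), dtype=bool)


def _gait_sequence(rng, rows: int, n_frames: int, dt: float,
                   walk_mean: float, pause_mean: float, out=None) -> np.ndarray:
    """Two-state (walk/pause) Markov chain equivalent to exponential bouts."""
    p_stop = -math.expm1(-dt / walk_mean)
    p_start = 1.0 if pause_mean == 0 else -math.expm1(-dt / pause_mean)
    frac = walk_mean / (walk_mean + pause_mean)
    walking = out if out is not None else np.empty((rows, n_frames), dtype=bool)
    state = rng.random(rows) < frac
    for t in range(n_frames):
        walking[:, t] = state
        u = rng.random(rows)
        state = np.where(state, u >= p_stop, u < p_start)
    return walking


def _fold_inplace(p: np.ndarray, length: float, scratch: np.ndarray) -> np.ndarray:
    np.multiply(p, np.float32(0.5 / length), out=scratch)
    np.rint(scratch, out=scratch)
    scratch *= np.float32(2.0 * length)
    p -= scratch
    np.abs(p, out=p)
    np.minimum(p, np.float32(length * (1.0 - 1e-9)), out=p)
    return p


def _paths(rng, rows: int, params: WalkParams,
           ws: "_Workspace | None" = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    arena = params.arena
    T, dt = arena.n_frames, arena.dt
    W, H = float(arena.width_px), float(arena.height_px)
    if ws is None:
        ws = _Workspace(rows, T)
    th = ws.step_a[:rows]
    v = ws.step_b[:rows]
    x = ws.x[:rows]
    y = ws.y[:rows]
    scratch = ws.scratch[:rows]
    walking = _gait_sequence(rng, rows, T, dt, params.walk_bout_mean_s,
                             params.pause_mean_s, out=ws.walking[:rows])
    # heading ~ wrapped normal, speed ~ log-normal, both i.i.d. per step
    rng.standard_normal(dtype=np.float32, out=th)
    th *= np.float32(params.heading.sd_rad)
    th += np.float32(params.heading.mean_rad)
    rng.standard_normal(dtype=np.float32, out=v)
    v *= np.float32(params.speed.sigma)
    np.exp(v, out=v)
    v *= np.float32(params.speed.median_px_s * dt)
    v *= walking[:, :-1]
    np.cos(th, out=x[:, 1:])
    x[:, 1:] *= v
    np.sin(th, out=th)
    th *= v
    x[:, 0] = 0.0
    y[:, 0] = 0.0
    np.cumsum(x[:, 1:], axis=1, out=x[:, 1:])
    np.cumsum(th, axis=1, out=y[:, 1:])
    x += rng.uniform(0, W, rows).astype(np.float32)[:, None]
    y += rng.uniform(0, H, rows).astype(np.float32)[:, None]
    return (_fold_inplace(x, W, scratch), _fold_inplace(y, H, scratch), walking)


def _zone_counts(x, y, walking, rect, mask, mask2) -> np.ndarray:
    """Per-row count of walking frames inside ``rect`` (buffers reused)."""
    np.greater_equal(x, np.float32(rect.x), out=mask)
    np.less(x, np.float32(rect.x + rect.w), out=mask2)
    mask &= mask2
    np.greater_equal(y, np.float32(rect.y), out=mask2)
    mask &= mask2
    np.less(y, np.float32(rect.y + rect.h), out=mask2)
    mask &= mask2
    mask &= walking
    return mask.sum(axis=1)


def simulate_walkers(n: int, params: WalkParams, seed: int) -> WalkerPaths:
    """Simulate ``n`` independent fictive walkers; reproducible given seed."""
    if n < 0:
        raise ValueError("n must be >= 0")
    T = params.arena.n_frames
    if n == 0:
        z = np.empty((0, T))
        return WalkerPaths(z, z.copy(), z.astype(bool), params.arena.fps)
    rng = np.random.default_rng(seed)
    x, y, walking = _paths(rng, n, params)
    return WalkerPaths(x, y, walking, params.arena.fps)


def walkers_to_table(paths: WalkerPaths, nominal_area_px2: int = 120) -> pd.DataFrame:
    """Flatten walker paths into a classified tracks table for the metrics layer."""
    n, T = paths.n_walkers, paths.n_frames
    frames = np.tile(np.arange(T), n)
    return pd.DataFrame({
        "frame": frames,
        "time_s": frames / paths.fps,
        "track_id": np.repeat(np.arange(n), T),
        "x_px": paths.x.ravel().astype(float),
        "y_px": paths.y.ravel().astype(float),
        "area_px": nominal_area_px2,
        "state": np.where(paths.walking.ravel(), "seeking", "stationary"),
    })


@dataclass
class StudyRow:
    """PI/HSI summary of repeated simulations at one walker count."""

    n: int
    iterations: int
    mean_pi: float
    sd_pi: float
    min_pi: float
    max_pi: float
    mean_hsi: float
    undefined_count: int


def pi_distribution(n: int, iterations: int, params: WalkParams, seed: int,
                    chunk_rows: int = 6000) -> StudyRow:
    """Distribution of the PI over repeated simulations with ``n`` walkers.

    Each iteration is scored like a real experiment (per-zone walking
    observations -> PI, all walking observations -> HSI).  Iterations with
    zero in-zone observations have an undefined PI; they are excluded from
    the moments and reported in ``undefined_count``.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if n < 0:
        raise ValueError("n must be >= 0")
    T = params.arena.n_frames
    if n == 0:
        return StudyRow(n, iterations, math.nan, math.nan, math.nan, math.nan,
                        0.0, iterations)
    z1, z2 = params.zones.zone1, params.zones.zone2
    ss = np.random.SeedSequence(seed)
    pis: list[np.ndarray] = []
    hsis: list[np.ndarray] = []
    undefined = 0
    done = 0
    chunk_iters = max(1, chunk_rows // n)
    ws = _Workspace(min(chunk_iters, iterations) * n, T)
    while done < iterations:
        k = min(chunk_iters, iterations - done)
        rng = np.random.default_rng(ss.spawn(1)[0])
        rows = k * n
        x, y, walking = _paths(rng, rows, params, ws)
        m, m2 = ws.mask[:rows], ws.mask2[:rows]
        o1 = _zone_counts(x, y, walking, z1, m, m2).reshape(k, n).sum(axis=1)
        o2 = _zone_counts(x, y, walking, z2, m, m2).reshape(k, n).sum(axis=1)
        tot = walking.sum(axis=1).reshape(k, n).sum(axis=1)
        denom = o1 + o2
        defined = denom > 0
        pis.append((o2[defined] - o1[defined]) / denom[defined])
        undefined += int((~defined).sum())
        hsis.append(tot / T)
        done += k
    pi = np.concatenate(pis)
    if len(pi) == 0:
        mean = sd = lo = hi = math.nan
    else:
        mean = float(pi.mean())
        sd = float(pi.std(ddof=1)) if len(pi) > 1 else math.nan
        lo, hi = float(pi.min()), float(pi.max())
    return StudyRow(n, iterations, mean, sd, lo, hi,
                    float(np.concatenate(hsis).mean()), undefined)


def run_variance_study(params: WalkParams | None = None, n_min: int = 1, n_max: int = 30,
                       iterations: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """PI-variance study across walker counts (default 1..30).

    Returns one row per walker count with the columns
    ``n,iterations,mean_pi,sd_pi,min_pi,max_pi,mean_hsi,undefined_count``.
    """
    params = params or WalkParams()
    seeds = np.random.SeedSequence(seed).spawn(n_max - n_min + 1)
    rows = []
    for n, ss in zip(range(n_min, n_max + 1), seeds):
        r = pi_distribution(n, iterations, params, ss.entropy % (2**31))
        rows.append([r.n, r.iterations, r.mean_pi, r.sd_pi, r.min_pi, r.max_pi,
                     r.mean_hsi, r.undefined_count])
    return pd.DataFrame(rows, columns=STUDY_COLUMNS)


def _isotonic_decreasing(values: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators projection onto non-increasing sequences."""
    vals = [-float(v) for v in values]  # solve the non-decreasing problem
    level: list[float] = []
    weight: list[int] = []
    for v in vals:
        level.append(v)
        weight.append(1)
        while len(level) > 1 and level[-2] > level[-1]:
            w = weight[-2] + weight[-1]
            m = (level[-2] * weight[-2] + level[-1] * weight[-1]) / w
            level[-2:] = [m]
            weight[-2:] = [w]
    out = np.concatenate([np.full(w, -m) for m, w in zip(level, weight)])
    return out


def min_hsi_threshold(study: pd.DataFrame, sd_gain_tolerance: float = 0.01) -> float:
    """Smallest mean HSI beyond which extra HSI barely reduces PI variance.

    The SD curve is first projected onto non-increasing sequences (the true
    SD provably shrinks with walker count, so this only removes Monte-Carlo
    noise and is a no-op on monotone input).  The rule then returns the
    first mean-HSI value from which every subsequent marginal SD reduction
    per unit HSI stays below ``sd_gain_tolerance``.  Raises if the study is
    too short, if mean HSI is not strictly increasing, or if the SD curve
    never plateaus within the studied range.
    """
    if len(study) < 3:
        raise ValueError("study too short to locate a variance plateau")
    h = np.asarray(study["mean_hsi"], dtype=float)
    s = np.asarray(study["sd_pi"], dtype=float)
    if not np.all(np.diff(h) > 0):
        raise ValueError("mean HSI must be strictly increasing across the study")
    s = _isotonic_decreasing(s)
    gains = (s[:-1] - s[1:]) / np.diff(h)
    suffix_max = np.maximum.accumulate(gains[::-1])[::-1]
    idx = np.flatnonzero(suffix_max < sd_gain_tolerance)
    if len(idx) == 0:
        raise ValueError("SD curve never plateaus within the studied HSI range")
    return float(h[idx[0]])
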