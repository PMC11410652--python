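"""Landed/flying and seeking/stationary classification of tracked objects.

Two filters turn raw tracks into host-seeking observations:

* an inclusive body-size window separates landed mosquitoes (large, opaque
  blobs) from flying ones, whose thresholded blobs are smaller;
* a smoothed-speed threshold separates walking ("seeking", the proxy for
  probing behaviour) from stationary mosquitoes, whose apparent speed is
  pure centroid jitter.

A ``landing_only`` mode scores every landed detection, for species that
land on a preferred zone without walking.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

MODES = ("walking", "landing_only")

#: Jitter/fps assumptions used to calibrate the default speed threshold;
#: they match the synthetic generator's defaults.
DEFAULT_JITTER_SD_PX = 0.5
DEFAULT_FPS = 10.0


def calibrate_speed_threshold(
    jitter_sd_px: float = DEFAULT_JITTER_SD_PX,
    fps: float = DEFAULT_FPS,
    smoothing_window: int = 5,
    quantile: float = 0.975,
    n_tracks: int = 400,
    track_len: int = 120,
    seed: int = 20240901,
) -> float:
    """Speed threshold as a high quantile of stationary (jitter-only) speeds.

    Simulates stationary tracks whose centroids jitter with the given SD,
    computes their smoothed speeds and returns the requested quantile.  With
    the threshold set there, at most ``1 - quantile`` of truly stationary
    detections are misread as seeking.  Deterministic (internal seed).
    """
    if jitter_sd_px < 0 or fps <= 0:
        raise ValueError("jitter_sd_px must be >= 0 and fps positive")
    if jitter_sd_px == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    speeds = []
    for _ in range(n_tracks):
        x = jitter_sd_px * rng.standard_normal(track_len)
        y = jitter_sd_px * rng.standard_normal(track_len)
        speeds.append(track_speeds(x, y, fps, smoothing_window))
    return float(np.quantile(np.concatenate(speeds), quantile))


@dataclass(frozen=True)
class FilterParams:
    """Size-window and speed-threshold parameters.

    ``speed_threshold_px_s=None`` resolves to the jitter-calibrated default
    (97.5th percentile of stationary smoothed speeds).
    """

    area_min: float = 50.0
    area_max: float = 400.0
    speed_threshold_px_s: float | None = None
    smoothing_window: int = 5
    mode: str = "walking"

    def __post_init__(self) -> None:
        if not (0 < self.area_min < self.area_max):
            raise ValueError("need 0 < area_min < area_max")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        if self.speed_threshold_px_s is not None and self.speed_threshold_px_s < 0:
            raise ValueError("speed_threshold_px_s must be >= 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    def resolved_speed_threshold(self, fps: float = DEFAULT_FPS) -> float:
        if self.speed_threshold_px_s is not None:
            return self.speed_threshold_px_s
        return calibrate_speed_threshold(fps=fps, smoothing_window=self.smoothing_window)


def area_filter(table: pd.DataFrame, params: FilterParams) -> pd.DataFrame:
    """Keep detections whose area lies in [area_min, area_max] (inclusive).

    Tracks are re-segmented wherever interior detections were removed: each
    remaining run of consecutive frames gets a fresh track id (original ids
    are kept in ``source_track_id``).
    """
    keep = table[(table["area_px"] >= params.area_min)
                 & (table["area_px"] <= params.area_max)].copy()
    keep = keep.sort_values(["track_id", "frame"], ignore_index=True)
    if len(keep) == 0:
        keep["source_track_id"] = keep.get("track_id", pd.Series(dtype="int64"))
        return keep
    new_track = ((keep["track_id"].diff() != 0) | (keep["frame"].diff() != 1)).cumsum() - 1
    keep["source_track_id"] = keep["track_id"]
    keep["track_id"] = new_track.astype(np.int64)
    return keep


def track_speeds(x, y, fps: float, smoothing_window: int = 5) -> np.ndarray:
    """Smoothed per-step speed series (px/s) of one track.

    Raw per-step speed is centroid displacement times fps; a centred moving
    average over ``smoothing_window`` steps (shrinking at the edges) damps
    jitter.  Tracks shorter than 2 points have no speeds.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be odd and >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        return np.empty(0)
    raw = np.hypot(np.diff(x), np.diff(y)) * fps
    if smoothing_window == 1:
        return raw
    return (pd.Series(raw)
            .rolling(smoothing_window, center=True, min_periods=1)
            .mean()
            .to_numpy())


def classify_seeking(table: pd.DataFrame, params: FilterParams, fps: float) -> pd.DataFrame:
    """Label every detection ``seeking`` or ``stationary``.

    In ``walking`` mode a detection is seeking iff its smoothed speed
    strictly exceeds the threshold (detection i carries the speed of the
    step ending at i; the first detection carries the first step's speed;
    single-detection tracks are stationary).  In ``landing_only`` mode every
    landed detection counts as seeking.
    """
    if params.mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    out = table.sort_values(["track_id", "frame"], ignore_index=True).copy()
    n = len(out)
    det_speed = np.zeros(n)
    if n:
        for _, idx in out.groupby("track_id").indices.items():
            s = track_speeds(out["x_px"].to_numpy()[idx], out["y_px"].to_numpy()[idx],
                             fps, params.smoothing_window)
            if len(s):
                det_speed[idx[0]] = s[0]
                det_speed[idx[1:]] = s
    out["smoothed_speed_px_s"] = det_speed
    if params.mode == "landing_only":
        out["state"] = "seeking"
    else:
        thr = params.resolved_speed_threshold(fps)
        out["state"] = np.where(det_speed > thr, "seeking", "stationary")
    return out
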