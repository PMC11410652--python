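"""Summary statistics of a two-choice host-seeking experiment.

Definitions
-----------
* **HSI** (host-seeking index): total seeking observations divided by the
  number of frames — the average number of mosquitoes seeking at any
  instant.
* **PI** (preference index): ``(obs_zone2 - obs_zone1) / (obs_zone1 +
  obs_zone2)``; PI < 0 prefers zone 1, PI > 0 prefers zone 2.  Identical
  whether computed from raw counts or per-zone HSIs (the frame count
  cancels).
* **IHSI**: per-timepoint seeker count in one zone averaged across
  experiments.
* **ATT / ATD / DTT**: per-zone bout statistics — average track (bout)
  time, average track distance, and total track count — each summarised as
  the normalised between-zone differential ``(m2 - m1)/(m1 + m2)`` in
  [-1, 1].
* **EAG amplitude**: post-stimulus peak deflection minus the pre-stimulus
  baseline mean.

Replicate aggregation follows the inclusion rule: a technical replicate
passes with HSI >= 5; a cage needs at least two passing replicates to enter
the analysis, and its summary is the mean over passing replicates.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import Rect, ZoneLayout

__all__ = [
    "ZoneLayout", "Rect", "assign_zone", "annotate_zones", "hsi",
    "preference_index", "ihsi_series", "seeking_counts_per_frame",
    "zone_track_differentials", "dwell_times", "ExperimentSummary",
    "summarize_experiment", "ReplicateSet", "CageSummary",
    "aggregate_replicates", "EAGTrace", "eag_amplitude",
]


def assign_zone(x: float, y: float, layout: ZoneLayout) -> int:
    """Zone membership of a position: 1, 2, or 0 for neither.

    Zones are half-open rectangles; a point on a zone's right or bottom
    edge is outside it.  Positions outside the frame raise.
    """
    if not (0 <= x < layout.frame_width and 0 <= y < layout.frame_height):
        raise ValueError(f"position ({x}, {y}) outside the frame")
    if layout.zone1.contains(x, y):
        return 1
    if layout.zone2.contains(x, y):
        return 2
    return 0


def annotate_zones(table: pd.DataFrame, layout: ZoneLayout) -> pd.DataFrame:
    """Vectorised zone assignment; adds a ``zone`` column (0 = neither)."""
    x = table["x_px"].to_numpy()
    y = table["y_px"].to_numpy()
    if len(table) and not (((x >= 0) & (x < layout.frame_width)
                            & (y >= 0) & (y < layout.frame_height)).all()):
        raise ValueError("positions outside the frame")
    zone = np.zeros(len(table), dtype=np.int64)
    zone[np.asarray(layout.zone1.contains(x, y), dtype=bool)] = 1
    zone[np.asarray(layout.zone2.contains(x, y), dtype=bool)] = 2
    out = table.copy()
    out["zone"] = zone
    return out


def hsi(observations: int, n_frames: int) -> float:
    """Host-seeking index: observations per frame (mean simultaneous seekers)."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if observations < 0:
        raise ValueError("observations must be >= 0")
    return observations / n_frames


def preference_index(obs_zone1: int, obs_zone2: int) -> float:
    """(obs2 - obs1) / (obs1 + obs2); undefined (error) with no observations."""
    if obs_zone1 < 0 or obs_zone2 < 0:
        raise ValueError("observation counts must be >= 0")
    total = obs_zone1 + obs_zone2
    if total == 0:
        raise ValueError("preference index undefined with zero observations in both zones")
    return (obs_zone2 - obs_zone1) / total


def seeking_counts_per_frame(table: pd.DataFrame, zone: int, n_frames: int) -> np.ndarray:
    """Per-frame count of seeking detections in the given zone."""
    sel = table[(table["state"] == "seeking") & (table["zone"] == zone)]
    return np.bincount(sel["frame"].to_numpy(), minlength=n_frames).astype(float)


def ihsi_series(experiments: Sequence[np.ndarray], smoothing_window: int | None = None) -> np.ndarray:
    """Instantaneous HSI: per-timepoint mean seeker count across experiments.

    Optionally smoothed with a centred moving average (odd window).
    """
    if len(experiments) == 0:
        raise ValueError("need at least one experiment")
    arr = np.asarray(experiments, dtype=float)
    if arr.ndim != 2:
        raise ValueError("experiments must share a common frame grid")
    series = arr.mean(axis=0)
    if smoothing_window is not None:
        if smoothing_window < 1 or smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        series = (pd.Series(series)
                  .rolling(smoothing_window, center=True, min_periods=1)
                  .mean().to_numpy())
    return series


def _differential(m1: float, m2: float) -> float:
    total = m1 + m2
    if total == 0:
        return 0.0
    return (m2 - m1) / total


def zone_track_differentials(table: pd.DataFrame, fps: float) -> tuple[float, float, float]:
    """Normalised between-zone differentials of bout statistics.

    A track (bout) is counted in a zone when it has at least one seeking
    detection there; a track crossing both zones counts once per zone.
    ATT_z = total seeking time in z / bouts in z; ATD_z = total seeking path
    length in z / bouts in z; DTT = (T2 - T1)/(T1 + T2) over bout counts.
    Requires the ``zone`` and ``state`` annotations.
    """
    seek = table[(table["state"] == "seeking") & (table["zone"] > 0)]
    if len(seek) == 0:
        raise ValueError("no seeking tracks in either zone")
    time_z = {1: 0.0, 2: 0.0}
    dist_z = {1: 0.0, 2: 0.0}
    count_z = {1: 0, 2: 0}
    for _, g in table.sort_values("frame").groupby("track_id"):
        zs = g["zone"].to_numpy()
        seeking = (g["state"] == "seeking").to_numpy()
        x = g["x_px"].to_numpy()
        y = g["y_px"].to_numpy()
        step = np.hypot(np.diff(x), np.diff(y)) if len(g) > 1 else np.empty(0)
        for z in (1, 2):
            inz = seeking & (zs == z)
            if inz.any():
                count_z[z] += 1
                time_z[z] += inz.sum() / fps
                # a step belongs to the zone of its starting detection
                dist_z[z] += step[inz[:-1]].sum() if len(step) else 0.0
    att_diff = _differential(
        time_z[1] / count_z[1] if count_z[1] else 0.0,
        time_z[2] / count_z[2] if count_z[2] else 0.0,
    )
    atd_diff = _differential(
        dist_z[1] / count_z[1] if count_z[1] else 0.0,
        dist_z[2] / count_z[2] if count_z[2] else 0.0,
    )
    dtt = _differential(count_z[1], count_z[2])
    return att_diff, atd_diff, dtt


def dwell_times(table: pd.DataFrame, layout: ZoneLayout, fps: float) -> pd.DataFrame:
    """Contiguous in-zone residence durations per track.

    Returns a table with columns ``track_id, zone, start_frame, duration_s``
    — one row per contiguous visit of a track to a zone.
    """
    t = table if "zone" in table.columns else annotate_zones(table, layout)
    rows = []
    for tid, g in t.sort_values("frame").groupby("track_id"):
        zs = g["zone"].to_numpy()
        frames = g["frame"].to_numpy()
        start = 0
        for i in range(1, len(zs) + 1):
            if i == len(zs) or zs[i] != zs[start] or frames[i] != frames[i - 1] + 1:
                if zs[start] > 0:
                    rows.append((tid, int(zs[start]), int(frames[start]), (i - start) / fps))
                start = i
    return pd.DataFrame(rows, columns=["track_id", "zone", "start_frame", "duration_s"])


@dataclass
class ExperimentSummary:
    """Per-experiment host-seeking observations and derived metrics."""

    obs_zone1: int
    obs_zone2: int
    n_frames: int
    hsi_total: float
    hsi_zone1: float
    hsi_zone2: float
    pi: float
    att_diff: float
    atd_diff: float
    dtt: float
    ihsi_zone1: np.ndarray = field(repr=False)
    ihsi_zone2: np.ndarray = field(repr=False)
    dwell: pd.DataFrame = field(repr=False)


def summarize_experiment(table: pd.DataFrame, layout: ZoneLayout,
                         n_frames: int, fps: float) -> ExperimentSummary:
    """Score one classified tracks table into an :class:`ExperimentSummary`.

    ``table`` needs ``state`` labels (from the classification step); zones
    are annotated here if absent.  Raises if there are no in-zone seeking
    observations at all (the PI is undefined there, by design).
    """
    t = table if "zone" in table.columns else annotate_zones(table, layout)
    seeking = t["state"] == "seeking"
    obs1 = int((seeking & (t["zone"] == 1)).sum())
    obs2 = int((seeking & (t["zone"] == 2)).sum())
    total_obs = int(seeking.sum())
    pi = preference_index(obs1, obs2)
    att_diff, atd_diff, dtt = zone_track_differentials(t, fps)
    return ExperimentSummary(
        obs_zone1=obs1, obs_zone2=obs2, n_frames=n_frames,
        hsi_total=hsi(total_obs, n_frames),
        hsi_zone1=hsi(obs1, n_frames), hsi_zone2=hsi(obs2, n_frames),
        pi=pi, att_diff=att_diff, atd_diff=atd_diff, dtt=dtt,
        ihsi_zone1=seeking_counts_per_frame(t, 1, n_frames),
        ihsi_zone2=seeking_counts_per_frame(t, 2, n_frames),
        dwell=dwell_times(t, layout, fps),
    )


@dataclass
class ReplicateSet:
    """Technical replicates of one cage plus the inclusion parameters."""

    cage_id: str
    replicates: list  # of ExperimentSummary (or anything with .hsi_total/.pi)
    min_hsi: float = 5.0
    min_passing: int = 2


@dataclass
class CageSummary:
    cage_id: str
    included: bool
    n_replicates: int
    n_passing: int
    mean_pi: float
    mean_hsi: float


def aggregate_replicates(rep_set: ReplicateSet) -> CageSummary:
    """Apply the replicate-inclusion rule and average the passing replicates.

    A replicate passes with HSI >= min_hsi (bound inclusive).  With fewer
    than ``min_passing`` passing replicates the cage is excluded and its
    means are NaN.
    """
    if not rep_set.replicates:
        raise ValueError("replicate set is empty")
    passing = [r for r in rep_set.replicates if r.hsi_total >= rep_set.min_hsi]
    included = len(passing) >= rep_set.min_passing
    if included:
        mean_pi = float(np.mean([r.pi for r in passing]))
        mean_hsi = float(np.mean([r.hsi_total for r in passing]))
    else:
        mean_pi = mean_hsi = math.nan
    return CageSummary(rep_set.cage_id, included, len(rep_set.replicates),
                       len(passing), mean_pi, mean_hsi)


@dataclass
class EAGTrace:
    """Uniformly sampled electroantennogram trace (mV) with a stimulus onset."""

    signal: np.ndarray
    rate_hz: float
    onset_s: float

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 1 or self.rate_hz <= 0:
            raise ValueError("signal must be 1-D with a positive sampling rate")


def eag_amplitude(trace: EAGTrace, pre_s: float = 5.0, post_s: float = 5.0,
                  polarity: str = "abs") -> float:
    """Stimulus-evoked amplitude: post-stimulus peak minus baseline mean.

    Baseline is the mean over [onset - pre_s, onset); the peak is the
    extremal deflection from baseline in (onset, onset + post_s].  Polarity
    'abs' (default) reports the magnitude of the largest absolute
    deflection; 'negative'/'positive' select one sign and report its
    magnitude.
    """
    i_on = int(round(trace.onset_s * trace.rate_hz))
    n_pre = int(round(pre_s * trace.rate_hz))
    n_post = int(round(post_s * trace.rate_hz))
    if i_on - n_pre < 0 or i_on + n_post > len(trace.signal):
        raise ValueError("trace too short for the requested pre/post windows")
    baseline = trace.signal[i_on - n_pre:i_on].mean()
    dev = trace.signal[i_on + 1:i_on + n_post + 1] - baseline
    if len(dev) == 0:
        raise ValueError("empty post-stimulus window")
    if polarity == "abs":
        return float(np.max(np.abs(dev)))
    if polarity == "positive":
        return float(np.max(dev))
    if polarity == "negative":
        return float(-np.min(dev))
    raise ValueError("polarity must be 'abs', 'positive' or 'negative'")
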