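"""Frame geometry: the recording grid and the two scoring zones.

Image coordinate convention used throughout the package: origin at the
top-left pixel, x increases rightward, y increases downward.  "Upward"
movement on the cage mesh therefore means decreasing y.
"""
from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ArenaSpec:
    """Recording geometry of a two-choice cage assay.

    Defaults match a 720 x 1280 px camera frame recorded at 10 frames per
    second for 5 minutes, i.e. 3,000 frames.
    """

    height_px: int = 720
    width_px: int = 1280
    fps: float = 10.0
    duration_s: float = 300.0

    def __post_init__(self) -> None:
        for name in ("height_px", "width_px", "fps", "duration_s"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v!r}")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))

    @property
    def dt(self) -> float:
        return 1.0 / self.fps

    @property
    def dimensions(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle; membership is half-open: [x, x+w) x [y, y+h)."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError("rectangle width and height must be positive")

    def contains(self, px, py):
        """Half-open membership test; works elementwise on arrays."""
        return (px >= self.x) & (px < self.x + self.w) & (py >= self.y) & (py < self.y + self.h)

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.x + self.w <= other.x
            or other.x + other.w <= self.x
            or self.y + self.h <= other.y
            or other.y + other.h <= self.y
        )


@dataclass(frozen=True)
class ZoneLayout:
    """The two rectangular scoring zones within the camera frame.

    The default places two 466 x 456 px zones symmetrically about the
    vertical midline of a 720 x 1280 frame, each centred within its half of
    the frame, preserving left/right neutrality.
    """

    zone1: Rect
    zone2: Rect
    frame_height: int = 720
    frame_width: int = 1280

    def __post_init__(self) -> None:
        for z in (self.zone1, self.zone2):
            if z.x < 0 or z.y < 0 or z.x + z.w > self.frame_width or z.y + z.h > self.frame_height:
                raise ValueError("scoring zone extends outside the frame")
        if self.zone1.overlaps(self.zone2):
            raise ValueError("scoring zones must be disjoint")

    @classmethod
    def default(
        cls,
        frame_height: int = 720,
        frame_width: int = 1280,
        zone_width: float = 466,
        zone_height: float = 456,
    ) -> "ZoneLayout":
        half = frame_width / 2.0
        mx = (half - zone_width) / 2.0
        my = (frame_height - zone_height) / 2.0
        if mx < 0 or my < 0:
            raise ValueError("zones do not fit in the frame")
        z1 = Rect(mx, my, zone_width, zone_height)
        z2 = Rect(half + mx, my, zone_width, zone_height)
        return cls(z1, z2, frame_height, frame_width)

    @classmethod
    def scaled(cls, frame_height: int, frame_width: int) -> "ZoneLayout":
        """Default layout rescaled proportionally to a smaller/larger frame."""
        zw = round(466 * frame_width / 1280)
        zh = round(456 * frame_height / 720)
        return cls.default(frame_height, frame_width, zw, zh)

    @property
    def zones(self) -> tuple[Rect, Rect]:
        return (self.zone1, self.zone2)
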