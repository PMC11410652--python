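"""Kinematic building blocks shared by the fictive-walker models.

Host-seeking mosquitoes walking on the cage mesh move mostly upward with no
left/right bias.  The walk model used here samples an independent speed and
heading per frame step: speeds are log-normal, headings wrapped-normal
centred on "up" (decreasing y in image coordinates).  Walkers are confined
to the frame by reflection at the borders.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Heading pointing up the mesh in image coordinates (y grows downward).
UP = -np.pi / 2


@dataclass(frozen=True)
class LogNormalSpeed:
    """Log-normal speed law parameterised by its median (px/s) and log-sd."""

    median_px_s: float = 25.0
    sigma: float = 0.5

    def __post_init__(self) -> None:
        if not (math.isfinite(self.median_px_s) and self.median_px_s > 0):
            raise ValueError("speed median must be finite and positive")
        if not (math.isfinite(self.sigma) and self.sigma >= 0):
            raise ValueError("speed sigma must be finite and non-negative")

    def sample(self, rng: np.random.Generator, size=None, dtype=np.float64) -> np.ndarray:
        z = rng.standard_normal(size, dtype=dtype)
        return self.median_px_s * np.exp(self.sigma * z)


@dataclass(frozen=True)
class WrappedNormalHeading:
    """Wrapped-normal heading; the default mean points up the mesh.

    Because headings enter only through cos/sin the wrap itself is
    immaterial.  A mean of exactly up (or down) makes the law left/right
    symmetric for any spread.
    """

    mean_rad: float = UP
    sd_rad: float = 0.8

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mean_rad) and math.isfinite(self.sd_rad) and self.sd_rad >= 0):
            raise ValueError("heading parameters must be finite with non-negative spread")

    def sample(self, rng: np.random.Generator, size=None, dtype=np.float64) -> np.ndarray:
        z = rng.standard_normal(size, dtype=dtype)
        return self.mean_rad + self.sd_rad * z


def fold(p: np.ndarray, length: float) -> np.ndarray:
    """Reflect unconstrained coordinates into [0, length).

    Reflecting a walk whose steps do not depend on position is equivalent to
    folding the unconstrained cumulative path, which lets callers build
    positions with a single cumsum.
    """
    # the folded coordinate is the distance to the nearest multiple of 2*length
    p = np.asarray(p)
    k = np.rint(p * (0.5 / length))
    out = np.abs(p - (2.0 * length) * k)
    # keep strictly inside the half-open frame interval
    return np.minimum(out, length * (1.0 - 1e-9))


def walk_path(
    rng: np.random.Generator,
    start_x: float,
    start_y: float,
    n_frames: int,
    dt: float,
    speed: LogNormalSpeed,
    heading: WrappedNormalHeading,
    width: float,
    height: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame positions of a single walker over ``n_frames`` frames."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if n_frames == 1:
        return (np.array([start_x]), np.array([start_y]))
    v = speed.sample(rng, n_frames - 1)
    th = heading.sample(rng, n_frames - 1)
    dx = v * dt * np.cos(th)
    dy = v * dt * np.sin(th)
    x = start_x + np.concatenate([[0.0], np.cumsum(dx)])
    y = start_y + np.concatenate([[0.0], np.cumsum(dy)])
    return fold(x, width), fold(y, height)
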