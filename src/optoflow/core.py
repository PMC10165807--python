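"""Shared containers: image sequences, activation regions, illumination schedules.

Conventions used across the package: row index = y (downward), column
index = x (rightward); x is the initial filament-alignment direction;
angles are measured CCW from +x; pixel centers sit at integer
coordinates and rectangular regions are half-open in pixel space.
Times are seconds, lengths micrometres, intensities uW/mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ImageSequence",
    "RectRegion",
    "Episode",
    "IlluminationSchedule",
]


@dataclass(frozen=True)
class RectRegion:
    """Axis-aligned rectangular activation region.

    ``length`` extends along x (the initial alignment direction),
    ``width`` along y. All fields in micrometres.
    """

    x0: float
    y0: float
    length: float
    width: float

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("region length and width must be positive")

    @property
    def x1(self) -> float:
        return self.x0 + self.length

    @property
    def y1(self) -> float:
        return self.y0 + self.width

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the half-open rectangle."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1)

    def pixel_slices(self, px_size: float, shape: tuple[int, int]) -> tuple[slice, slice]:
        """(row, col) slices of the region on a pixel grid, clipped to ``shape``."""
        r0 = max(int(np.ceil(self.y0 / px_size - 1e-9)), 0)
        r1 = min(int(np.ceil(self.y1 / px_size - 1e-9)), shape[0])
        c0 = max(int(np.ceil(self.x0 / px_size - 1e-9)), 0)
        c1 = min(int(np.ceil(self.x1 / px_size - 1e-9)), shape[1])
        if r1 <= r0 or c1 <= c0:
            raise ValueError("region does not overlap the frame")
        return slice(r0, r1), slice(c0, c1)


@dataclass(frozen=True)
class Episode:
    """One illumination episode: light on in ``region`` (None = full frame)."""

    t_start: float
    t_end: float
    intensity: float
    region: RectRegion | None = None

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("episode must have t_end > t_start")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")


@dataclass
class IlluminationSchedule:
    """Time-ordered, non-overlapping illumination episodes.

    Gaps between episodes (and any time before/after them) are dark.
    """

    episodes: list[Episode] = field(default_factory=list)

    def __post_init__(self) -> None:
        eps = sorted(self.episodes, key=lambda e: e.t_start)
        for a, b in zip(eps, eps[1:]):
            if b.t_start < a.t_end:
                raise ValueError(
                    f"overlapping episodes: [{a.t_start}, {a.t_end}) and "
                    f"[{b.t_start}, {b.t_end})"
                )
        self.episodes = eps

    @property
    def t_start(self) -> float:
        if not self.episodes:
            raise ValueError("empty schedule")
        return self.episodes[0].t_start

    @property
    def t_end(self) -> float:
        if not self.episodes:
            raise ValueError("empty schedule")
        return self.episodes[-1].t_end

    def episode_at(self, t: float) -> Episode | None:
        for ep in self.episodes:
            if ep.t_start <= t < ep.t_end:
                return ep
        return None

    def intensity_at(self, t) -> np.ndarray | float:
        """Illumination intensity (uW/mm^2) at time(s) t; 0 when dark."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(t_arr)
        for ep in self.episodes:
            out[(t_arr >= ep.t_start) & (t_arr < ep.t_end)] = ep.intensity
        return out if np.ndim(t) else float(out[0])

    def on_seconds(self, t: float) -> float:
        """Cumulative illuminated time in [min(0, t_start), t]."""
        total = 0.0
        for ep in self.episodes:
            if ep.intensity <= 0:
                continue
            total += max(0.0, min(t, ep.t_end) - ep.t_start)
        return total


@dataclass
class ImageSequence:
    """Time-ordered stack of 2-D fluorescence frames.

    frames: float array (T, H, W); px_size_um: pixel size; dt_s: frame
    interval; t0_s: timestamp of the first frame.
    """

    frames: np.ndarray
    px_size_um: float
    dt_s: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.px_size_um <= 0 or self.dt_s <= 0:
            raise ValueError("px_size_um and dt_s must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + self.dt_s * np.arange(len(self))


def cycles_schedule(
    n_cycles: int,
    on_s: float,
    off_s: float,
    intensity: float,
    region: RectRegion | None = None,
    start_dark_s: float = 0.0,
) -> IlluminationSchedule:
    """Convenience constructor for alternating dark/light cycles.

    Each cycle is ``off_s`` of dark followed by ``on_s`` of light at
    ``intensity``; an optional extra dark lead-in precedes the first cycle.
    """
    eps = []
    t = start_dark_s
    for _ in range(n_cycles):
        t += off_s
        eps.append(Episode(t, t + on_s, intensity, region))
        t += on_s
    return IlluminationSchedule(eps)
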