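"""The Track container: time-ordered positions of one cell.

Tracks are the interchange object between detection/tracking and all the
downstream physics: per-step velocities, trajectory-average effective
radius, and U-turn candidates all derive from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Track"]


@dataclass
class Track:
    """Time-ordered cell positions with per-frame area.

    Coordinates are metric (µm, mathematical orientation); ``t`` is in
    seconds and ``frame`` holds the originating frame indices (strictly
    increasing; gaps allowed up to the tracker's ``max_gap``).
    """

    track_id: int
    frame: np.ndarray
    t: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    area_um2: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        for name in ("t", "x_um", "y_um", "area_um2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.frame)
        if any(len(getattr(self, a)) != n
               for a in ("t", "x_um", "y_um", "area_um2")):
            raise ValueError("all per-frame arrays must have equal length")
        if np.any(np.diff(self.frame) <= 0):
            raise ValueError("frames within a track must strictly increase")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) in µm."""
        return np.column_stack([self.x_um, self.y_um])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def mean_radius(self) -> float:
        """Trajectory-average effective radius, µm (mean of per-frame
        sqrt(area/pi))."""
        return float(np.mean(np.sqrt(self.area_um2 / np.pi)))

    def mean_speed(self) -> float:
        """Mean step speed, µm/s (chord length over time, forward steps)."""
        if len(self) < 2:
            return 0.0
        d = np.hypot(np.diff(self.x_um), np.diff(self.y_um))
        return float(np.sum(d) / (self.t[-1] - self.t[0]))

    def slice_time(self, t0: float, t1: float) -> "Track":
        """Sub-track with t0 <= t <= t1 (same id, shared metadata)."""
        m = (self.t >= t0) & (self.t <= t1)
        return Track(self.track_id, self.frame[m], self.t[m], self.x_um[m],
                     self.y_um[m], self.area_um2[m], dict(self.meta))
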