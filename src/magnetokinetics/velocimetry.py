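"""Velocity and radius statistics from reconstructed tracks.

Per-step speeds come from central differences of the track positions;
per-step (radius, log10 speed) instances populate Freedman–Diaconis-binned
relative-frequency histograms.  A compliance filter can restrict
statistics to cells that actually followed the guiding field; it is off
by default so that all detected motion is included.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .tracks import Track

logger = logging.getLogger(__name__)

__all__ = ["track_velocities", "fd_bin_width", "fd_bin_edges",
           "joint_histogram", "velocity_samples", "mf_compliance_filter",
           "passive_flag", "track_summary", "PASSIVE_SPEED_UM_S"]

#: speeds below this are consistent with passive (non-swimming) motion, µm/s
PASSIVE_SPEED_UM_S = 7.0


def track_velocities(track: Track) -> np.ndarray:
    """Per-step speeds, µm/s, by central differences over timestamps.

    A track of n points yields n-2 speeds (endpoints dropped); tracks
    shorter than 2 yield an empty array.
    """
    n = len(track)
    if n < 2:
        return np.array([])
    if n == 2:
        return np.array([])
    dx = track.x_um[2:] - track.x_um[:-2]
    dy = track.y_um[2:] - track.y_um[:-2]
    dt = track.t[2:] - track.t[:-2]
    return np.hypot(dx, dy) / dt


def fd_bin_width(samples: np.ndarray) -> float:
    """Freedman–Diaconis bin width, 2 * IQR * n^(-1/3).

    Falls back to the Sturges rule (range / (log2 n + 1)) when the IQR is
    zero, with a log message.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        logger.info("zero IQR; falling back to Sturges binning")
        rng = np.ptp(x)
        if rng == 0:
            raise ValueError("degenerate (constant) sample")
        return float(rng / (np.log2(len(x)) + 1))
    return float(2.0 * iqr * len(x) ** (-1.0 / 3.0))


def fd_bin_edges(samples: np.ndarray) -> np.ndarray:
    """Bin edges covering the sample range at the FD width."""
    x = np.asarray(samples, dtype=float)
    w = fd_bin_width(x)
    lo, hi = float(x.min()), float(x.max())
    n_bins = max(int(np.ceil((hi - lo) / w)), 1)
    return lo + np.arange(n_bins + 1) * w


def velocity_samples(tracks: Sequence[Track]) -> pd.DataFrame:
    """Per-step (r_um, v_um_s) instances pooled over tracks.

    The radius paired with each step is the track's trajectory average
    (per-step footprints are noisy; the trajectory mean is the radius
    estimate used throughout).
    """
    rows = []
    for tr in tracks:
        v = track_velocities(tr)
        if len(v) == 0:
            continue
        r = tr.mean_radius()
        rows.append(pd.DataFrame({"track_id": tr.track_id, "r_um": r,
                                  "v_um_s": v}))
    if not rows:
        return pd.DataFrame(columns=["track_id", "r_um", "v_um_s"])
    return pd.concat(rows, ignore_index=True)


def joint_histogram(samples: np.ndarray, log10_velocity: bool = True
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D relative-frequency histogram with FD bins per axis.

    ``samples`` is (n, 2) with columns (radius, speed); with
    ``log10_velocity`` the speed axis is binned in log10 units.  Returns
    (grid, r_edges, v_edges); the grid sums to 1.
    """
    pts = np.asarray(samples, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need an (n>=2, 2) sample array")
    r, v = pts[:, 0], pts[:, 1]
    if log10_velocity:
        if np.any(v <= 0):
            keep = v > 0
            r, v = r[keep], v[keep]
        v = np.log10(v)
    r_edges = fd_bin_edges(r)
    v_edges = fd_bin_edges(v)
    grid, _, _ = np.histogram2d(r, v, bins=[r_edges, v_edges])
    grid = grid / grid.sum()
    return grid, r_edges, v_edges


def mf_compliance_filter(tracks: Sequence[Track],
                         field_axis: Sequence[float],
                         tolerance_deg: float) -> list[Track]:
    """Keep tracks whose net displacement direction lies within
    ``tolerance_deg`` of ``field_axis``.

    ``field_axis`` should be the direction cells are expected to swim
    (after the guiding field was reversed).  Off by default in the
    pipeline: published statistics include all detected motion.
    """
    axis = np.asarray(field_axis, dtype=float)
    axis = axis / np.hypot(*axis)
    cos_tol = np.cos(np.deg2rad(tolerance_deg))
    kept = []
    for tr in tracks:
        d = np.array([tr.x_um[-1] - tr.x_um[0], tr.y_um[-1] - tr.y_um[0]])
        n = np.hypot(*d)
        if n == 0:
            continue
        if (d / n) @ axis >= cos_tol:
            kept.append(tr)
    return kept


def passive_flag(speed_um_s, threshold: float = PASSIVE_SPEED_UM_S):
    """True where a speed is consistent with passive motion (< ~7 µm/s,
    strict inequality at the boundary).  A label only — never a filter."""
    flag = np.asarray(speed_um_s, dtype=float) < threshold
    return bool(flag) if flag.ndim == 0 else flag


def track_summary(tracks: Sequence[Track]) -> pd.DataFrame:
    """Per-track mean speed, radius and passive label."""
    rows = []
    for tr in tracks:
        v = track_velocities(tr)
        mean_v = float(np.mean(v)) if len(v) else 0.0
        rows.append({"track_id": tr.track_id, "n_points": len(tr),
                     "r_um": tr.mean_radius(), "v_um_s": mean_v,
                     "passive": bool(mean_v < PASSIVE_SPEED_UM_S)})
    return pd.DataFrame(rows, columns=["track_id", "n_points", "r_um",
                                       "v_um_s", "passive"])
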