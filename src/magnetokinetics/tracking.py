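"""Gated global-nearest-neighbour tracking with constant-velocity
prediction.

Detections are linked frame by frame: each live track predicts its next
position from the average velocity of its last few steps, candidate
track-detection pairs inside a gate are assigned by a globally optimal
(Hungarian) matching on distance (optionally plus an area-similarity
term), unmatched detections seed new tracks, and tracks missing for more
than ``max_gap`` frames are closed.  The same Track contract accepts
externally produced trajectory tables, so a heavier offline
multiple-hypothesis tracker can be swapped in upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detection import Detection
from .tracks import Track
from .units import px_to_um

__all__ = ["TrackingParams", "TrackBuilder", "predict", "link_frame",
           "build_tracks", "association_accuracy"]

_BIG = 1e12


@dataclass(frozen=True)
class TrackingParams:
    """Linking parameters (pixel units unless noted)."""

    v_max_px: float = 40.0        # gate speed, px per frame interval
    gate_slack_px: float = 4.0
    velocity_window: int = 3      # steps averaged for prediction
    area_weight: float = 0.0      # lambda for |dA|/A term in the cost
    max_gap: int = 2              # frames a track may go unmatched
    min_track_length: int = 10
    pixel_size_um: float = 1.0
    frame_rate: float = 50.0


@dataclass
class _LiveTrack:
    track_id: int
    frames: list[int]
    xs: list[float]
    ys: list[float]
    areas: list[float]
    missed: int = 0

    @property
    def last(self) -> tuple[float, float]:
        return self.xs[-1], self.ys[-1]


def predict(track: "_LiveTrack | Track", dt_frames: float,
            params: TrackingParams | None = None
            ) -> tuple[np.ndarray, float]:
    """Constant-velocity extrapolation and gate radius (px).

    Velocity is the average of the last ``velocity_window`` steps; a
    single-point track predicts its own position with the full gate.
    """
    params = params or TrackingParams()
    if isinstance(track, Track):
        xs, ys, frames = track.x_um, track.y_um, track.frame  # already metric
    else:
        xs, ys, frames = track.xs, track.ys, track.frames
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    frames = np.asarray(frames, dtype=float)
    gate = params.v_max_px * dt_frames + params.gate_slack_px
    if len(xs) < 2:
        return np.array([xs[-1], ys[-1]]), gate
    k = min(params.velocity_window, len(xs) - 1)
    dt = frames[-1] - frames[-1 - k]
    vx = (xs[-1] - xs[-1 - k]) / dt
    vy = (ys[-1] - ys[-1 - k]) / dt
    pred = np.array([xs[-1] + vx * dt_frames, ys[-1] + vy * dt_frames])
    return pred, gate


def link_frame(live: list[_LiveTrack], detections: Sequence[Detection],
               dt_frames: float, params: TrackingParams,
               next_id: int) -> tuple[list[_LiveTrack], int]:
    """One assignment step; returns updated live tracks and next free id."""
    dets = list(detections)
    preds, gates = [], []
    for tr in live:
        p, g = predict(tr, dt_frames + tr.missed, params)
        preds.append(p)
        gates.append(g)
    assigned_det = set()
    if live and dets:
        cost = np.full((len(live), len(dets)), _BIG)
        for i, (p, g) in enumerate(zip(preds, gates)):
            for j, d in enumerate(dets):
                dist = np.hypot(d.x_px - p[0], d.y_px - p[1])
                if dist <= g:
                    c = dist
                    if params.area_weight > 0:
                        a0 = live[i].areas[-1]
                        c += params.area_weight * abs(d.area_px2 - a0) / a0
                    cost[i, j] = c
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if cost[i, j] >= _BIG:
                continue
            d = dets[j]
            live[i].frames.append(d.frame)
            live[i].xs.append(d.x_px)
            live[i].ys.append(d.y_px)
            live[i].areas.append(d.area_px2)
            live[i].missed = 0
            assigned_det.add(j)
    # increment miss counters for tracks that did not receive a detection
    current_frame = dets[0].frame if dets else None
    for tr in live:
        if current_frame is None or tr.frames[-1] != current_frame:
            tr.missed += 1
    for j, d in enumerate(dets):
        if j not in assigned_det:
            live.append(_LiveTrack(next_id, [d.frame], [d.x_px], [d.y_px],
                                   [d.area_px2]))
            next_id += 1
    return live, next_id


def build_tracks(detections_per_frame: Sequence[Sequence[Detection]],
                 params: TrackingParams | None = None) -> list[Track]:
    """Link per-frame detections into metric tracks.

    Deterministic: identical detections and parameters give identical
    tracks.  Tracks shorter than ``min_track_length`` are dropped; output
    coordinates are converted to µm (mathematical orientation) using
    ``pixel_size_um`` and timestamps from ``frame_rate``.
    """
    params = params or TrackingParams()
    live: list[_LiveTrack] = []
    closed: list[_LiveTrack] = []
    next_id = 0
    prev_frame: int | None = None
    for fi, dets in enumerate(detections_per_frame):
        dt_frames = 1.0 if prev_frame is None else float(fi - prev_frame)
        live, next_id = link_frame(live, list(dets), dt_frames, params,
                                   next_id)
        still = []
        for tr in live:
            if tr.missed > params.max_gap:
                closed.append(tr)
            else:
                still.append(tr)
        live = still
        prev_frame = fi
    closed.extend(live)

    out: list[Track] = []
    for tr in sorted(closed, key=lambda t: t.track_id):
        if len(tr.frames) < params.min_track_length:
            continue
        x_um, y_um = px_to_um(tr.xs, tr.ys, params.pixel_size_um)
        t = np.asarray(tr.frames, dtype=float) / params.frame_rate
        area_um2 = np.asarray(tr.areas, dtype=float) * params.pixel_size_um**2
        out.append(Track(tr.track_id, tr.frames, t, x_um, y_um, area_um2))
    return out


def association_accuracy(tracks: Sequence[Track], truth: "pd.DataFrame",
                         pixel_size_um: float,
                         match_radius_px: float = 2.0) -> float:
    """Fraction of correctly associated links, scored against ground truth.

    Each track point is matched to the nearest ground-truth cell in its
    frame (within ``match_radius_px``); a link (consecutive pair of points
    in a track) counts as correct when both endpoints match the same
    ground-truth cell.
    """
    from .units import um_to_px

    by_frame = {f: g for f, g in truth.groupby("frame")}
    n_links = 0
    n_correct = 0
    for tr in tracks:
        x_px, y_px = um_to_px(tr.x_um, tr.y_um, pixel_size_um)
        ids = []
        for k, f in enumerate(tr.frame):
            g = by_frame.get(int(f))
            if g is None or not len(g):
                ids.append(None)
                continue
            d = np.hypot(g["x_px"].to_numpy() - x_px[k],
                         g["y_px"].to_numpy() - y_px[k])
            j = int(np.argmin(d))
            ids.append(int(g["cell_id"].iloc[j])
                       if d[j] <= match_radius_px else None)
        for a, b in zip(ids, ids[1:]):
            n_links += 1
            if a is not None and a == b:
                n_correct += 1
    return n_correct / n_links if n_links else float("nan")
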