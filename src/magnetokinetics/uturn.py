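"""U-turn decomposition and magnetic-moment estimation.

A square-wave field forces one U-turn per reversal.  Each track is cut
into per-reversal segments, rotated into a canonical frame where the turn
follows y = -(L/pi) ln(sec(pi x / L)), and the asymptotic width L is
fitted by nonlinear least squares.  The moment follows from
m = pi alpha v / (B L) with the segment's own mean speed and the track's
trajectory-average effective radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .physics import (FieldProtocol, MediumParams, UTurnFit,
                      moment_from_uturn)
from .tracks import Track

__all__ = ["UTurnParams", "Segment", "MomentEstimate", "segment_uturns",
           "canonicalize", "fit_uturn_width", "estimate_moment",
           "estimate_moments"]

NON_MAGNETIC = "non-magnetic or unfit"


@dataclass(frozen=True)
class UTurnParams:
    """Segmentation/fit thresholds (all configurable, all logged in the
    estimate's flags)."""

    min_points: int = 10
    settle_angle_deg: float = 5.0
    min_turn_angle_deg: float = 90.0   # net heading change to call it a turn
    max_residual: float = 0.05         # normalized RMS misfit
    max_width_um: float | None = None  # e.g. half the field-of-view diagonal
    # a completed, settled turn spans nearly its full width in x; a much
    # larger fitted width means the points only cover the apex of some
    # wider curve (e.g. an incomplete turn or a circular arc)
    max_width_extent_ratio: float = 1.2
    heading_smooth: int = 3
    aggregate: str = "mean"            # or "median" across U-turns


@dataclass
class Segment:
    """One U-turn candidate: points from a reversal until settling."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pre_heading: np.ndarray            # unit vector, heading before reversal
    reversal_time: float

    def __len__(self) -> int:
        return len(self.t)

    def mean_speed(self) -> float:
        d = np.hypot(np.diff(self.x), np.diff(self.y))
        dt = self.t[-1] - self.t[0]
        return float(np.sum(d) / dt) if dt > 0 else 0.0


@dataclass
class MomentEstimate:
    """Per-track U-turn magnetometry result (µm, µm/s, A·m² units)."""

    track_id: int
    radius_um: float
    speed_um_s: float
    drag: float
    widths_um: list[float] = field(default_factory=list)
    moments_Am2: list[float] = field(default_factory=list)
    moment_Am2: float = np.nan
    n_uturns: int = 0
    eligible: bool = False
    reason: str = ""


def _headings(x: np.ndarray, y: np.ndarray, smooth: int = 1) -> np.ndarray:
    """Unit step-heading vectors, optionally boxcar-smoothed."""
    dx, dy = np.diff(x), np.diff(y)
    if smooth > 1 and len(dx) >= smooth:
        kern = np.ones(smooth) / smooth
        dx = np.convolve(dx, kern, mode="same")
        dy = np.convolve(dy, kern, mode="same")
    norm = np.hypot(dx, dy)
    norm[norm == 0] = 1.0
    return np.column_stack([dx / norm, dy / norm])


def segment_uturns(track: Track, field_protocol: FieldProtocol | None,
                   params: UTurnParams | None = None) -> list[Segment]:
    """Cut a track into per-reversal U-turn candidates.

    Each candidate spans from a reversal time to the earlier of the next
    reversal and the moment the heading settles within
    ``settle_angle_deg`` of the new field direction.  Candidates shorter
    than ``min_points`` or without a genuine heading reversal (net turn
    below ``min_turn_angle_deg``) are discarded — a non-magnetic cell
    ignores every reversal and yields no candidates.  With no protocol,
    reversal times are detected from heading flips along the track.
    """
    params = params or UTurnParams()
    if len(track) < 3:
        return []
    if field_protocol is not None and field_protocol.mode == "static":
        return []
    if field_protocol is not None:
        reversal_times = [rt for rt in field_protocol.reversal_times
                          if track.t[0] < rt < track.t[-1]]
        new_dirs = [_field_dir_after(field_protocol, rt)
                    for rt in reversal_times]
    else:
        reversal_times = _detect_reversals(track, params)
        new_dirs = [None] * len(reversal_times)

    segs: list[Segment] = []
    h = _headings(track.x_um, track.y_um, params.heading_smooth)
    t_mid = 0.5 * (track.t[:-1] + track.t[1:])
    for k, rt in enumerate(reversal_times):
        t_end = reversal_times[k + 1] if k + 1 < len(reversal_times) \
            else track.t[-1]
        pre = h[t_mid < rt]
        if len(pre) == 0:
            continue
        measured_pre = _mean_dir(pre[-3:])
        if new_dirs[k] is not None:
            # the turn's approach asymptote is the old field direction
            # (phase phi -> pi), which the instantaneous heading only
            # approximates when the cell had fully settled
            new_dir = new_dirs[k]
            pre_heading = -new_dir
            if measured_pre @ pre_heading < 0:
                # track was swimming against the field (south-seeking or
                # unsettled); fall back to the measured heading
                pre_heading = measured_pre
        else:
            pre_heading = measured_pre
            new_dir = -pre_heading
        # settle point: heading within settle_angle of the new direction
        in_win = (t_mid >= rt) & (t_mid <= t_end)
        idx = np.nonzero(in_win)[0]
        settle_cos = np.cos(np.deg2rad(params.settle_angle_deg))
        t_settle = t_end
        for i in idx:
            if h[i] @ new_dir >= settle_cos:
                t_settle = t_mid[i]
                break
        m = (track.t >= rt) & (track.t <= t_settle)
        if m.sum() < params.min_points:
            continue
        seg = Segment(track.t[m], track.x_um[m], track.y_um[m],
                      pre_heading, rt)
        # require an actual turn: final heading must have flipped
        hs = _headings(seg.x, seg.y, params.heading_smooth)
        if len(hs) == 0:
            continue
        turn = np.rad2deg(np.arccos(np.clip(pre_heading @ _mean_dir(hs[-3:]),
                                            -1, 1)))
        if turn < params.min_turn_angle_deg:
            continue
        segs.append(seg)
    return segs


def _field_dir_after(fp: FieldProtocol, t_rev: float) -> np.ndarray:
    ang = float(fp.direction_angle(t_rev + 1e-12))
    return np.array([np.cos(ang), np.sin(ang)])


def _mean_dir(h: np.ndarray) -> np.ndarray:
    v = h.mean(axis=0)
    n = np.hypot(*v)
    return v / n if n > 0 else np.array([1.0, 0.0])


def _detect_reversals(track: Track, params: UTurnParams) -> list[float]:
    """Fallback reversal detection without a protocol.

    Mid-turn crossings are found as sign flips of the heading projected on
    the dominant swimming axis; each crossing is then backtracked to the
    local minimum of the angular deviation from the pre-turn direction —
    the deviation shrinks while the cell is still settling toward the old
    field direction and grows once the turn has started, so the minimum
    marks the reversal itself.
    """
    # unsmoothed headings: a boxcar would smear the turn onset by a frame
    h = _headings(track.x_um, track.y_um, 1)
    t_mid = 0.5 * (track.t[:-1] + track.t[1:])
    # dominant swimming axis as the axial (angle-doubled) circular mean:
    # settled headings dominate, mid-turn samples average out
    theta = np.arctan2(h[:, 1], h[:, 0])
    z = np.exp(2j * theta)
    axis_angle = 0.5 * np.angle(np.mean(z))
    for _ in range(3):
        # refine on the settled subset: mid-turn headings bias the mean
        settled = np.abs(np.sin(theta - axis_angle)) < 0.1
        if settled.sum() < max(len(theta) // 10, 4):
            break
        axis_angle = 0.5 * np.angle(np.mean(z[settled]))
    axis = np.array([np.cos(axis_angle), np.sin(axis_angle)])
    proj = h @ axis
    sign = np.sign(proj)
    sign[sign == 0] = 1
    flips = list(np.nonzero(np.diff(sign) != 0)[0])
    # distance of the heading from the axis LINE: minimal at a reversal,
    # maximal (~1) at the mid-turn crossing
    off_axis = np.abs(h[:, 0] * axis[1] - h[:, 1] * axis[0])
    times: list[float] = []
    prev_flip = 0
    for f in flips:
        # reference direction: the most-settled headings before this turn
        win = np.arange(prev_flip, f)
        if len(win) == 0:
            prev_flip = f
            continue
        k = min(10, len(win))
        ref_idx = win[np.argsort(off_axis[win])[:k]]
        ref = _mean_dir(h[ref_idx])
        dev = np.arccos(np.clip(h[prev_flip:f + 1] @ ref, -1, 1))
        i = len(dev) - 1
        while i > 0 and dev[i - 1] <= dev[i]:
            i -= 1
        t = float(t_mid[prev_flip + i])
        if not times or t - times[-1] > 3 * np.median(np.diff(track.t)):
            times.append(t)
        prev_flip = f
    return times


def canonicalize(segment: Segment) -> tuple[np.ndarray, np.ndarray]:
    """Rotate/translate a segment into the U-turn shape frame.

    The pre-reversal heading maps onto +y (the approach leg of
    y = -(L/pi) ln sec(pi x/L) climbs toward the apex), the apex (maximal
    y) is translated to the origin.  Degenerate (near-zero extent)
    segments raise ValueError.
    """
    hx, hy = segment.pre_heading
    # rotation taking (hx, hy) -> (0, 1)
    rot = np.array([[hy, -hx], [hx, hy]])
    pts = rot @ np.vstack([segment.x, segment.y])
    x, y = pts
    if np.ptp(x) < 1e-9 or np.ptp(y) < 1e-9:
        raise ValueError("degenerate segment: no lateral extent")
    apex = int(np.argmax(y))
    return x - x[apex], y - y[apex]


_U_CUT = np.pi / 2 - 1e-5  # beyond this the log-sec model extends linearly


def _shape_residuals(p: np.ndarray, x: np.ndarray, y: np.ndarray
                     ) -> np.ndarray:
    """Approximately-perpendicular misfit of the log-sec U-turn shape.

    The raw vertical misfit is divided by sqrt(1 + y'(x)^2): near the
    asymptotes the curve is almost vertical and a vertical residual wildly
    amplifies any lateral offset, which both biases the fit and traps the
    optimizer.  Outside |pi (x-x0)/L| = pi/2 the model is extended
    linearly (C1), keeping a useful gradient instead of a flat clip.
    """
    width, x0, y0 = p
    u = np.pi * (x - x0) / width
    au = np.abs(u)
    model = np.empty_like(u)
    inside = au < _U_CUT
    model[inside] = np.log(np.cos(au[inside]))
    model[~inside] = np.log(np.cos(_U_CUT)) \
        - np.tan(_U_CUT) * (au[~inside] - _U_CUT)
    slope = np.tan(np.minimum(au, _U_CUT))
    vert = (width / np.pi) * model + y0 - y
    return vert / np.hypot(1.0, slope)


def fit_uturn_width(points: tuple[np.ndarray, np.ndarray],
                    params: UTurnParams | None = None) -> UTurnFit:
    """Least-squares fit of the U-turn shape over (L, x-offset, y-offset).

    The initial width is the observed x-extent; the residual is the RMS
    misfit normalized by the fitted width.  Non-convergence or a residual
    above ``max_residual`` flags rejection instead of raising.
    """
    params = params or UTurnParams()
    x, y = (np.asarray(a, dtype=float) for a in points)
    n = len(x)
    if n < 3:
        return UTurnFit(width=np.nan, x=x, y=y, residual=np.inf,
                        n_points=n, accepted=False, reason="too few points")
    extent = float(np.ptp(x))
    p0 = np.array([max(extent * 1.05, 1e-3),
                   float((x.max() + x.min()) / 2), 0.0])
    try:
        res = least_squares(_shape_residuals, p0, args=(x, y),
                            bounds=([1e-6, x.min() - extent, -np.inf],
                                    [100 * max(extent, 1e-3),
                                     x.max() + extent, np.inf]),
                            max_nfev=2000)
    except Exception:                                     # noqa: BLE001
        return UTurnFit(width=np.nan, x=x, y=y, residual=np.inf, n_points=n,
                        accepted=False, reason="fit failed")
    width = float(res.x[0])
    rms = float(np.sqrt(np.mean(res.fun**2)))
    norm_res = rms / width if width > 0 else np.inf
    accepted = bool(res.success) and norm_res <= params.max_residual
    reason = "" if accepted else "residual above threshold"
    if accepted and width > params.max_width_extent_ratio * extent:
        accepted, reason = False, "turn not completed (width >> extent)"
    if params.max_width_um is not None and width > params.max_width_um:
        accepted, reason = False, "width exceeds field of view"
    return UTurnFit(width=width, x=x, y=y, residual=norm_res, n_points=n,
                    accepted=accepted, reason=reason)


def estimate_moment(track: Track, field_protocol: FieldProtocol,
                    medium: MediumParams | None = None,
                    params: UTurnParams | None = None) -> MomentEstimate:
    """Full per-track U-turn magnetometry.

    Per eligible U-turn: m = pi alpha v_segment / (B L); the track moment
    aggregates over eligible turns (mean by default).  Tracks with no
    eligible turn are excluded with reason "non-magnetic or unfit".
    """
    params = params or UTurnParams()
    medium = medium or MediumParams()
    radius = track.mean_radius()
    est = MomentEstimate(track_id=track.track_id, radius_um=radius,
                         speed_um_s=track.mean_speed(),
                         drag=_drag(radius, medium))
    segments = segment_uturns(track, field_protocol, params)
    for seg in segments:
        try:
            pts = canonicalize(seg)
        except ValueError:
            continue
        fit = fit_uturn_width(pts, params)
        if not fit.accepted:
            continue
        v_seg = seg.mean_speed()
        if v_seg <= 0:
            continue
        m = moment_from_uturn(fit.width, v_seg, radius,
                              field_protocol.magnitude, medium.viscosity)
        est.widths_um.append(fit.width)
        est.moments_Am2.append(m)
    est.n_uturns = len(est.moments_Am2)
    if est.n_uturns >= 1:
        agg = np.median if params.aggregate == "median" else np.mean
        est.moment_Am2 = float(agg(est.moments_Am2))
        est.eligible = True
    else:
        est.reason = NON_MAGNETIC
    return est


def _drag(radius_um: float, medium: MediumParams) -> float:
    from .physics import rotational_drag

    return rotational_drag(radius_um, medium.viscosity)


def estimate_moments(tracks: Sequence[Track],
                     field_protocol: FieldProtocol,
                     medium: MediumParams | None = None,
                     params: UTurnParams | None = None) -> pd.DataFrame:
    """Apply :func:`estimate_moment` to many tracks; tidy result table."""
    rows = []
    for tr in tracks:
        e = estimate_moment(tr, field_protocol, medium, params)
        rows.append({"track_id": e.track_id, "r_um": e.radius_um,
                     "v_um_s": e.speed_um_s, "m_Am2": e.moment_Am2,
                     "n_uturns": e.n_uturns, "eligible": e.eligible,
                     "reason": e.reason})
    return pd.DataFrame(rows, columns=["track_id", "r_um", "v_um_s",
                                       "m_Am2", "n_uturns", "eligible",
                                       "reason"])
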