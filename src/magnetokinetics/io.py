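"""File formats: TIFF stacks, track tables, field protocols.

Track tables use the interchange header
(track_id, frame, t_s, x_um, y_um, area_um2) — comma-separated, UTF-8,
'.' decimal, units embedded in the column names — so externally produced
trajectories (e.g. an offline multiple-hypothesis tracker's exports) can
be ingested unchanged.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .physics import FieldProtocol
from .tracks import Track

__all__ = ["read_stack", "write_stack", "read_tracks", "write_tracks",
           "read_protocol", "write_protocol"]

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um", "area_um2"]


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page grayscale TIFF as a (frames, h, w) array.

    RGB input is rejected (convert to grayscale upstream); mixed frame
    shapes and unreadable files are fatal.
    """
    path = Path(path)
    try:
        stack = tifffile.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read TIFF stack {path}: {exc}") from exc
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None, ...]
    if stack.ndim != 3:
        if stack.ndim == 4 and stack.shape[-1] in (3, 4):
            raise ValueError(f"{path} looks like RGB(A); convert to "
                             "grayscale first (e.g. average the channels)")
        raise ValueError(f"{path}: expected a grayscale stack, got shape "
                         f"{stack.shape}")
    if stack.shape[-1] in (3, 4) and stack.shape[-1] < 5:
        raise ValueError(f"{path} looks like RGB(A); convert to grayscale "
                         "first (e.g. average the channels)")
    return stack


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(stack))


def write_tracks(path: str | Path, tracks: Sequence[Track]) -> None:
    """Write tracks in the interchange CSV format."""
    frames = [pd.DataFrame({"track_id": tr.track_id, "frame": tr.frame,
                            "t_s": tr.t, "x_um": tr.x_um, "y_um": tr.y_um,
                            "area_um2": tr.area_um2}) for tr in tracks]
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=TRACK_COLUMNS))
    df.to_csv(Path(path), index=False)


def read_tracks(path: str | Path) -> list[Track]:
    """Read the interchange CSV back into Track objects.

    Rows may arrive in any order (they are sorted per track); a missing
    column or a duplicated (track, frame) pair is fatal.
    """
    df = pd.read_csv(Path(path))
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) "
                         f"{', '.join(missing)}")
    if df.duplicated(["track_id", "frame"]).any():
        raise ValueError(f"{path}: duplicate (track_id, frame) rows")
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        tracks.append(Track(int(tid), g["frame"].to_numpy(),
                            g["t_s"].to_numpy(), g["x_um"].to_numpy(),
                            g["y_um"].to_numpy(), g["area_um2"].to_numpy()))
    return tracks


def write_protocol(path: str | Path, protocol: FieldProtocol) -> None:
    data = {"magnitude_T": protocol.magnitude,
            "axis": list(protocol.axis), "mode": protocol.mode,
            "reversal_times_s": list(protocol.reversal_times)}
    Path(path).write_text(yaml.safe_dump(data))


def read_protocol(path: str | Path) -> FieldProtocol:
    """Field protocol from YAML (magnitude_T, axis, mode,
    reversal_times_s)."""
    data = yaml.safe_load(Path(path).read_text())
    try:
        return FieldProtocol(magnitude=float(data["magnitude_T"]),
                             axis=tuple(data.get("axis", (1.0, 0.0))),
                             mode=data.get("mode", "static"),
                             reversal_times=tuple(
                                 data.get("reversal_times_s", ())))
    except KeyError as exc:
        raise ValueError(f"{path}: missing protocol field {exc}") from exc
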