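"""Unit conventions and conversions.

External quantities are carried in microscopy-friendly units (positions and
radii in µm, speeds in µm/s, field in tesla, viscosity in Pa·s, moments in
A·m²); physics formulas evaluate in SI internally.  All conversions live
here so that no other module multiplies by 1e-6 by hand.

Pixel coordinates are 0-based with the origin at the top-left corner, x
rightward and y downward (image convention).  Metric coordinates use the
mathematical orientation (y upward); the flip happens exactly once, in
:func:`px_to_um` / :func:`um_to_px`.
"""

from __future__ import annotations

import numpy as np

UM_PER_M = 1e6
M_PER_UM = 1e-6


def um_to_m(x_um):
    """Micrometres to metres (scalars or arrays)."""
    return np.asarray(x_um, dtype=float) * M_PER_UM


def m_to_um(x_m):
    """Metres to micrometres."""
    return np.asarray(x_m, dtype=float) * UM_PER_M


def px_to_um(x_px, y_px, pixel_size_um: float):
    """Image-convention pixel coordinates to metric coordinates.

    y is negated so that metric coordinates are mathematically oriented
    (y increases upward).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    return (np.asarray(x_px, dtype=float) * pixel_size_um,
            -np.asarray(y_px, dtype=float) * pixel_size_um)


def um_to_px(x_um, y_um, pixel_size_um: float):
    """Inverse of :func:`px_to_um` (returns float pixel coordinates)."""
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    return (np.asarray(x_um, dtype=float) / pixel_size_um,
            -np.asarray(y_um, dtype=float) / pixel_size_um)
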