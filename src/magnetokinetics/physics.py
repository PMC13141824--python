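"""Bean-model swimming physics for magnetotactic bacteria (MTB).

An MTB is treated as a self-propelled magnetic dipole: it swims at constant
speed ``v`` along its body axis while the magnetic torque ``-m B sin(phi)``
relaxes the body axis toward the applied field against rotational viscous
drag ``alpha``:

    alpha * dphi/dt = -m * B * sin(phi),      dx/dt = v * (cos th, sin th)

where ``phi`` is the angle between body axis and field.  Reversing the
field forces a U-turn whose asymptotic width

    L = pi * v * alpha / (m * B)

encodes the magnetic moment; the turn's path in a canonical frame follows

    y = -(L / pi) * ln(sec(pi * x / L)).

Units: µm, µm/s, seconds and tesla at the API surface; SI internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Literal, Sequence

import numpy as np

from .tracks import Track
from .units import um_to_m

__all__ = [
    "MediumParams",
    "FieldProtocol",
    "CellState",
    "UTurnFit",
    "rotational_drag",
    "effective_radius",
    "uturn_shape",
    "moment_from_uturn",
    "uturn_width_theory",
    "heading_closed_form",
    "simulate_trajectory",
]

#: dynamic viscosity of the aqueous medium used in the experiments, Pa·s
DEFAULT_VISCOSITY = 0.90e-3
#: flux density of the pulsed / static field used in the experiments, tesla
DEFAULT_FIELD_T = 2.55e-4
#: post-reversal misalignment, rad.  Exact anti-alignment with the new field
#: is an unstable equilibrium of the heading equation (zero torque), so the
#: simulator nudges the heading by this much at each reversal.
REVERSAL_MISALIGNMENT = 1e-3

DragConvention = Literal["paper", "sphere"]


@dataclass(frozen=True)
class MediumParams:
    """Properties of the swimming medium.

    Parameters
    ----------
    viscosity : float
        Dynamic viscosity, Pa·s.  Defaults to 0.90e-3 Pa·s (water at the
        experiment temperature).
    """

    viscosity: float = DEFAULT_VISCOSITY

    def __post_init__(self) -> None:
        if not self.viscosity > 0:
            raise ValueError(f"viscosity must be > 0, got {self.viscosity}")


@dataclass(frozen=True)
class FieldProtocol:
    """The applied magnetic field over time.

    Parameters
    ----------
    magnitude : float
        Flux density B, tesla (the strength is constant; only the direction
        switches).
    axis : sequence of 2 floats
        Unit vector of the field axis in the image plane.
    mode : {"static", "square_wave"}
    reversal_times : sequence of float
        Strictly increasing times (s) at which a square-wave field flips
        direction; empty for a static field.
    """

    magnitude: float = DEFAULT_FIELD_T
    axis: tuple[float, float] = (1.0, 0.0)
    mode: Literal["static", "square_wave"] = "static"
    reversal_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("field magnitude must be >= 0")
        ax = np.asarray(self.axis, dtype=float)
        if ax.shape != (2,) or not np.isclose(np.hypot(*ax), 1.0, atol=1e-8):
            raise ValueError("axis must be a unit 2-vector")
        object.__setattr__(self, "axis", (float(ax[0]), float(ax[1])))
        rt = tuple(float(t) for t in self.reversal_times)
        if any(b <= a for a, b in zip(rt, rt[1:])):
            raise ValueError("reversal_times must be strictly increasing")
        if self.mode == "static" and rt:
            raise ValueError("static protocol cannot carry reversal times")
        object.__setattr__(self, "reversal_times", rt)

    @classmethod
    def square_wave(cls, magnitude: float, half_period: float,
                    n_reversals: int, first_reversal: float | None = None,
                    axis: Sequence[float] = (1.0, 0.0)) -> "FieldProtocol":
        """Square wave with evenly spaced reversals."""
        t0 = half_period if first_reversal is None else first_reversal
        times = tuple(t0 + k * half_period for k in range(n_reversals))
        return cls(magnitude=magnitude, axis=tuple(axis),
                   mode="square_wave", reversal_times=times)

    def sign(self, t) -> np.ndarray:
        """Direction sign (+1/-1) along ``axis`` at time ``t`` (starts +1)."""
        n_flips = np.searchsorted(np.asarray(self.reversal_times), t,
                                  side="right")
        return np.where(n_flips % 2 == 0, 1.0, -1.0)

    def direction_angle(self, t) -> np.ndarray:
        """Angle (rad, mathematical orientation) of the field at time ``t``."""
        base = np.arctan2(self.axis[1], self.axis[0])
        return np.where(self.sign(t) > 0, base, base + np.pi)


@dataclass(frozen=True)
class CellState:
    """Kinematic and magnetic state of one cell.

    position : (x, y) µm; heading : angle of body axis relative to the field
    axis, rad; speed : µm/s; moment : A·m²; radius : effective radius, µm.
    """

    position: tuple[float, float] = (0.0, 0.0)
    heading: float = 0.0
    speed: float = 20.0
    moment: float = 1.0e-15
    radius: float = 0.6

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if not self.radius > 0:
            raise ValueError("radius must be > 0")
        if self.moment < 0:
            raise ValueError("moment must be >= 0")


@dataclass(frozen=True)
class UTurnFit:
    """Result of fitting the U-turn shape function to one turn.

    width : asymptotic U-turn width L, µm; x, y : canonical-frame points,
    µm; residual : RMS misfit normalized by L (dimensionless).
    """

    width: float
    x: np.ndarray = dataclass_field(repr=False, default=None)
    y: np.ndarray = dataclass_field(repr=False, default=None)
    residual: float = np.nan
    n_points: int = 0
    accepted: bool = True
    reason: str = ""


def rotational_drag(radius_um, viscosity: float = DEFAULT_VISCOSITY,
                    convention: DragConvention = "paper"):
    """Rotational drag coefficient alpha (SI, kg·m²/s ≡ N·m·s).

    ``convention="paper"`` uses alpha = 8 pi² eta R³ (the form the U-turn
    moment calibration was published with); ``"sphere"`` uses the classic
    rigid-sphere value 8 pi eta R³.  The two differ by a factor of pi.

    Parameters
    ----------
    radius_um : float or array
        Effective cell radius, µm.
    viscosity : float
        Dynamic viscosity, Pa·s.
    """
    radius_um = np.asarray(radius_um, dtype=float)
    if np.any(radius_um <= 0):
        raise ValueError("radius must be > 0")
    if not viscosity > 0:
        raise ValueError("viscosity must be > 0")
    if convention not in ("paper", "sphere"):
        raise ValueError(f"unknown drag convention {convention!r}")
    factor = 8 * np.pi**2 if convention == "paper" else 8 * np.pi
    alpha = factor * viscosity * um_to_m(radius_um) ** 3
    return float(alpha) if alpha.ndim == 0 else alpha


def effective_radius(area_um2):
    """Radius (µm) of the circle with the same area as the cell footprint."""
    area_um2 = np.asarray(area_um2, dtype=float)
    if np.any(area_um2 <= 0):
        raise ValueError("area must be > 0")
    r = np.sqrt(area_um2 / np.pi)
    return float(r) if r.ndim == 0 else r


def uturn_shape(x, width):
    """Theoretical U-turn path y(x) = -(L/pi) ln(sec(pi x / L)).

    Even in x, zero at the apex (x=0) and unbounded below as |x| -> L/2.
    ``x`` and the returned y are in the same length unit as ``width``.
    """
    if not width > 0:
        raise ValueError("width must be > 0")
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) >= width / 2):
        raise ValueError("|x| must be < width/2 (the legs are asymptotes)")
    y = (width / np.pi) * np.log(np.cos(np.pi * x / width))
    return float(y) if y.ndim == 0 else y


def moment_from_uturn(width_um, speed_um_s, radius_um, field_t: float,
                      viscosity: float = DEFAULT_VISCOSITY,
                      convention: DragConvention = "paper"):
    """Magnetic moment (A·m²) from a fitted asymptotic U-turn width.

    m = pi * alpha * v / (B * L), with alpha = rotational_drag(R).
    """
    width_um = np.asarray(width_um, dtype=float)
    speed_um_s = np.asarray(speed_um_s, dtype=float)
    if np.any(width_um <= 0):
        raise ValueError("width must be > 0")
    if np.any(speed_um_s <= 0):
        raise ValueError("speed must be > 0")
    if not field_t > 0:
        raise ValueError("field must be > 0")
    alpha = rotational_drag(radius_um, viscosity, convention)
    m = (np.pi * alpha * um_to_m(speed_um_s)
         / (field_t * um_to_m(width_um)))
    return float(m) if np.ndim(m) == 0 else m


def uturn_width_theory(moment, speed_um_s, radius_um, field_t: float,
                       viscosity: float = DEFAULT_VISCOSITY,
                       convention: DragConvention = "paper"):
    """Asymptotic U-turn width L = pi v alpha / (m B), in µm (exact inverse
    of :func:`moment_from_uturn`)."""
    if np.any(np.asarray(moment) <= 0):
        raise ValueError("moment must be > 0 for a finite U-turn width")
    alpha = rotational_drag(radius_um, viscosity, convention)
    width_m = np.pi * um_to_m(speed_um_s) * alpha / (np.asarray(moment) * field_t)
    w = width_m * 1e6
    return float(w) if np.ndim(w) == 0 else w


def relaxation_time(moment, radius_um, field_t: float,
                    viscosity: float = DEFAULT_VISCOSITY,
                    convention: DragConvention = "paper") -> float:
    """Orientational relaxation time tau = alpha / (m B), seconds."""
    if not moment > 0:
        raise ValueError("moment must be > 0")
    return rotational_drag(radius_um, viscosity, convention) / (moment * field_t)


def heading_closed_form(phi0: float, t, tau: float):
    """Closed-form solution of alpha dphi/dt = -m B sin(phi).

    tan(phi(t)/2) = tan(phi0/2) * exp(-t/tau) with tau = alpha/(m B).
    Valid for phi0 in (0, pi); phi relaxes monotonically to 0.
    """
    t = np.asarray(t, dtype=float)
    phi = 2.0 * np.arctan(np.tan(phi0 / 2.0) * np.exp(-t / tau))
    return float(phi) if phi.ndim == 0 else phi


def _heading_rate(theta: float, dir_angle: float, inv_tau: float) -> float:
    return -inv_tau * np.sin(theta - dir_angle)


def simulate_trajectory(cell: CellState, field: FieldProtocol,
                        medium: MediumParams | None = None, *,
                        dt: float, duration: float,
                        rotational_noise: float = 0.0,
                        seed: int | None = None,
                        substeps: int = 10,
                        convention: DragConvention = "paper",
                        track_id: int = 0) -> Track:
    """Integrate Bean-model swimming under a field protocol.

    The heading ODE is integrated with fixed-step RK4 at ``dt/substeps``;
    the track is sampled every ``dt`` (the frame interval).  Optional
    rotational diffusion (``rotational_noise``, rad²/s) adds white noise to
    the heading between deterministic substeps.  Per-frame area is the
    constant pi R².

    At each field reversal the heading is additionally nudged by
    ``REVERSAL_MISALIGNMENT`` so a perfectly anti-aligned cell still
    responds (the anti-aligned state carries zero torque).
    """
    if medium is None:
        medium = MediumParams()
    if not dt > 0:
        raise ValueError("dt must be > 0")
    if duration < dt:
        raise ValueError("duration must be >= dt")
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    rng = np.random.default_rng(seed)

    if cell.moment > 0 and field.magnitude > 0:
        inv_tau = 1.0 / relaxation_time(cell.moment, cell.radius,
                                        field.magnitude, medium.viscosity,
                                        convention)
    else:
        inv_tau = 0.0

    n_frames = int(np.floor(duration / dt)) + 1
    h = dt / substeps
    theta = float(field.direction_angle(0.0)) + cell.heading
    x, y = map(float, cell.position)
    v = cell.speed
    sigma_dtheta = np.sqrt(2.0 * rotational_noise * h)

    times = np.arange(n_frames) * dt
    xs = np.empty(n_frames)
    ys = np.empty(n_frames)
    xs[0], ys[0] = x, y
    reversals = list(field.reversal_times)
    next_rev = 0

    t = 0.0
    for i in range(1, n_frames):
        for _ in range(substeps):
            # apply any reversal falling inside this substep
            while next_rev < len(reversals) and reversals[next_rev] <= t + h:
                if inv_tau > 0:
                    theta += REVERSAL_MISALIGNMENT
                next_rev += 1
            dir_angle = float(field.direction_angle(t + h / 2))
            # RK4 on the joint (theta, x, y) system
            k1t = _heading_rate(theta, dir_angle, inv_tau)
            k1x, k1y = v * np.cos(theta), v * np.sin(theta)
            th2 = theta + h / 2 * k1t
            k2t = _heading_rate(th2, dir_angle, inv_tau)
            k2x, k2y = v * np.cos(th2), v * np.sin(th2)
            th3 = theta + h / 2 * k2t
            k3t = _heading_rate(th3, dir_angle, inv_tau)
            k3x, k3y = v * np.cos(th3), v * np.sin(th3)
            th4 = theta + h * k3t
            k4t = _heading_rate(th4, dir_angle, inv_tau)
            k4x, k4y = v * np.cos(th4), v * np.sin(th4)
            theta += h / 6 * (k1t + 2 * k2t + 2 * k3t + k4t)
            x += h / 6 * (k1x + 2 * k2x + 2 * k3x + k4x)
            y += h / 6 * (k1y + 2 * k2y + 2 * k3y + k4y)
            if sigma_dtheta > 0:
                theta += sigma_dtheta * rng.standard_normal()
            t += h
        xs[i], ys[i] = x, y

    area = np.full(n_frames, np.pi * cell.radius**2)
    return Track(track_id=track_id, frame=np.arange(n_frames),
                 t=times, x_um=xs, y_um=ys, area_um2=area)
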