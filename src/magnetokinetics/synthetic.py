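"""Ground-truth generators: populations, U-turn track sets, rendered stacks.

These generators replace archived microscopy data in every test: cells are
drawn from bivariate Gaussian populations in (log10 speed, radius) space,
swum through the Bean-model simulator under a field protocol, and — when
image-level behaviour is under test — rendered into grayscale stacks with
controlled illumination and noise nuisances.  Each generator emits the
ground truth needed to score detection (centroids/areas), tracking
(identities) and moment estimation (v, R, m, theoretical U-turn width).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .physics import (CellState, FieldProtocol, MediumParams,
                      simulate_trajectory, uturn_width_theory)
from .tracks import Track
from .units import um_to_px

__all__ = [
    "GaussianComponent",
    "PopulationSpec",
    "RenderSpec",
    "sample_population",
    "gen_uturn_dataset",
    "render_stack",
    "DAY1_VELOCIMETRY_COMPONENTS",
    "DAY2_VELOCIMETRY_COMPONENTS",
    "MOMENT_RADIUS_COMPONENTS",
    "CRITICAL_RADIUS_UM",
]


@dataclass(frozen=True)
class GaussianComponent:
    """One bivariate Gaussian population in (axis1, axis2) space.

    For velocimetry populations axis1 is log10 speed (log10 µm/s) and axis2
    the effective radius (µm); for moment/radius populations axis1 is the
    moment (1e-15 A·m²) and axis2 the radius (µm).
    """

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    rho: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigmas must be > 0")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")

    @property
    def cov(self) -> np.ndarray:
        c = self.rho * self.sigma1 * self.sigma2
        return np.array([[self.sigma1**2, c], [c, self.sigma2**2]])


# Fitted population parameters of the heterogeneous Ogre River sample
# (means/sigmas/correlations in (log10 ||v|| [µm/s], r [µm]) space), used as
# the generator's reference parameterizations.  Component weights were not
# published; equal weights are the default.
DAY1_VELOCIMETRY_COMPONENTS: tuple[GaussianComponent, ...] = (
    GaussianComponent(0.98, 0.402, 0.40, 0.081, -0.49),
    GaussianComponent(1.348, 0.5379, 0.223, 0.0247, 0.30),
    GaussianComponent(1.429, 0.686, 0.165, 0.127, -0.046),
    GaussianComponent(0.806, 0.519, 0.26, 0.167, 0.51),
)
DAY2_VELOCIMETRY_COMPONENTS: tuple[GaussianComponent, ...] = (
    GaussianComponent(0.38, 0.439, 0.49, 0.103, 0.28),
    GaussianComponent(0.288, 0.751, 0.239, 0.265, -0.16),
)
# Moment/radius populations: axis1 = m in 1e-15 A·m², axis2 = r in µm.
MOMENT_RADIUS_COMPONENTS: tuple[GaussianComponent, ...] = (
    GaussianComponent(1.314, 0.784, 0.413, 0.062, 0.60),
    GaussianComponent(1.63, 0.9017, 0.49, 0.0279, -0.26),
    GaussianComponent(2.35, 0.941, 0.99, 0.099, 0.816),
)
#: critical effective radius below which cells carry no measurable moment, µm
CRITICAL_RADIUS_UM = 0.57


@dataclass(frozen=True)
class PopulationSpec:
    """A mixture of bivariate Gaussian cell populations.

    ``components`` live in (log10 speed, radius) space.  The magnetic
    moment is assigned either per component (``moment_model="gaussian"``,
    using ``moment_mean``/``moment_sd`` in A·m²) or by the size law
    ``moment_model="linear"``: m = moment_slope * (R - critical_radius),
    clipped at zero (cells below the critical radius are non-magnetic).
    """

    components: tuple[GaussianComponent, ...] = DAY1_VELOCIMETRY_COMPONENTS
    n_cells: int = 1000
    moment_model: Literal["gaussian", "linear"] = "linear"
    moment_mean: tuple[float, ...] | None = None
    moment_sd: tuple[float, ...] | None = None
    moment_slope: float = 5.0e-15       # A·m² per µm above critical radius
    critical_radius: float = CRITICAL_RADIUS_UM
    min_radius: float = 0.05            # truncation floor, µm

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        if not comps:
            raise ValueError("need at least one component")
        w = np.array([c.weight for c in comps], dtype=float)
        if w.sum() <= 0:
            raise ValueError("weights must sum to a positive value")
        object.__setattr__(self, "components", comps)
        if self.moment_model == "gaussian":
            if self.moment_mean is None or self.moment_sd is None:
                raise ValueError("gaussian moment model needs mean and sd")
            if len(self.moment_mean) != len(comps) \
                    or len(self.moment_sd) != len(comps):
                raise ValueError("per-component moment mean/sd required")

    @property
    def weights(self) -> np.ndarray:
        w = np.array([c.weight for c in self.components], dtype=float)
        return w / w.sum()


@dataclass(frozen=True)
class RenderSpec:
    """How synthetic cells are drawn into a grayscale stack.

    The spot model is an isotropic Gaussian with sigma =
    ``spot_sigma_factor * R / pixel_size`` — an arbitrary stand-in for the
    real (undocumented) cell appearance; total spot flux is proportional to
    the cell area.  A linear illumination gradient and Poisson/read noise
    are optional nuisances; ``stuck_fraction`` adds motionless decoy cells.
    """

    shape: tuple[int, int] = (256, 256)     # (height, width) px
    pixel_size_um: float = 0.25
    frame_rate: float = 50.0
    # 1/sqrt(2 ln 2): the spot's half-max footprint then equals the cell's
    # equal-area disk, tying the rendered appearance to the area it encodes
    spot_sigma_factor: float = 0.8493
    flux_per_area: float = 2000.0           # counts per µm² of cell area
    background: float = 100.0
    gradient_amplitude: float = 0.0         # peak-to-peak linear gradient
    read_noise: float = 0.0                 # Gaussian sigma, counts
    poisson_noise: bool = False
    stuck_fraction: float = 0.0
    dtype: str = "uint16"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.frame_rate <= 0:
            raise ValueError("pixel size and frame rate must be > 0")

    def spot_sigma_px(self, radius_um: float) -> float:
        return self.spot_sigma_factor * radius_um / self.pixel_size_um

    def peak_amplitude(self, radius_um: float) -> float:
        """Peak counts of a cell's spot above background."""
        area = np.pi * radius_um**2
        sig = self.spot_sigma_px(radius_um)
        return self.flux_per_area * area / (2 * np.pi * sig**2)

    def snr(self, radius_um: float) -> float:
        """Peak amplitude over total noise sigma at background level."""
        noise_var = self.read_noise**2
        if self.poisson_noise:
            noise_var += self.background
        if noise_var == 0:
            return np.inf
        return self.peak_amplitude(radius_um) / np.sqrt(noise_var)


def sample_population(spec: PopulationSpec, seed: int | None = None
                      ) -> list[CellState]:
    """Draw cells component-wise from the mixture; reproducible per seed."""
    rng = np.random.default_rng(seed)
    comps = spec.components
    idx = rng.choice(len(comps), size=spec.n_cells, p=spec.weights)
    cells: list[CellState] = []
    for i in idx:
        c = comps[i]
        log10v, radius = rng.multivariate_normal((c.mu1, c.mu2), c.cov)
        radius = max(radius, spec.min_radius)
        speed = 10.0 ** log10v
        if spec.moment_model == "linear":
            m = max(spec.moment_slope * (radius - spec.critical_radius), 0.0)
        else:
            m = max(rng.normal(spec.moment_mean[i], spec.moment_sd[i]), 0.0)
        cells.append(CellState(position=(0.0, 0.0), heading=0.0,
                               speed=speed, moment=m, radius=radius))
    return cells


def sample_component_points(components: Sequence[GaussianComponent],
                            n: int, seed: int | None = None) -> np.ndarray:
    """(n, 2) sample from the mixture itself (no physics attached) —
    used to emulate published 2D histogram data sets directly."""
    rng = np.random.default_rng(seed)
    comps = list(components)
    w = np.array([c.weight for c in comps], dtype=float)
    w = w / w.sum()
    idx = rng.choice(len(comps), size=n, p=w)
    out = np.empty((n, 2))
    for k, c in enumerate(comps):
        m = idx == k
        if m.any():
            out[m] = rng.multivariate_normal((c.mu1, c.mu2), c.cov,
                                             size=int(m.sum()))
    return out


def gen_uturn_dataset(spec: PopulationSpec, field_protocol: FieldProtocol,
                      n_reversals: int | None = None, dt: float = 0.02,
                      seed: int | None = None, *,
                      medium: MediumParams | None = None,
                      rotational_noise: float = 0.0,
                      position_noise_um: float = 0.0,
                      settle_time: float = 1.0,
                      spread_um: float = 0.0,
                      ) -> tuple[list[Track], pd.DataFrame]:
    """Simulate one track per cell spanning a square-wave protocol.

    Returns the tracks and a ground-truth table with columns
    (cell_id, v_um_s, r_um, m_Am2, L_theory_um); L_theory is NaN for
    non-magnetic cells.  ``position_noise_um`` adds i.i.d. Gaussian
    measurement noise to the sampled coordinates.
    """
    if field_protocol.mode != "square_wave" or not field_protocol.reversal_times:
        raise ValueError("U-turn datasets need a square-wave protocol")
    if medium is None:
        medium = MediumParams()
    rng = np.random.default_rng(seed)
    cells = sample_population(spec, seed=rng.integers(2**31))
    revs = field_protocol.reversal_times
    if n_reversals is not None:
        revs = revs[:n_reversals]
    duration = revs[-1] + settle_time

    tracks: list[Track] = []
    rows = []
    for cid, cell in enumerate(cells):
        if spread_um > 0:
            pos = tuple(rng.uniform(-spread_um, spread_um, size=2))
            cell = CellState(position=pos, heading=cell.heading,
                             speed=cell.speed, moment=cell.moment,
                             radius=cell.radius)
        tr = simulate_trajectory(
            cell, field_protocol, medium, dt=dt, duration=duration,
            rotational_noise=rotational_noise,
            seed=int(rng.integers(2**31)), track_id=cid)
        if position_noise_um > 0:
            tr.x_um = tr.x_um + rng.normal(0, position_noise_um, len(tr))
            tr.y_um = tr.y_um + rng.normal(0, position_noise_um, len(tr))
        tracks.append(tr)
        if cell.moment > 0:
            width = uturn_width_theory(cell.moment, cell.speed, cell.radius,
                                       field_protocol.magnitude,
                                       medium.viscosity)
        else:
            width = np.nan
        rows.append({"cell_id": cid, "v_um_s": cell.speed,
                     "r_um": cell.radius, "m_Am2": cell.moment,
                     "L_theory_um": width})
    return tracks, pd.DataFrame(rows)


def render_stack(tracks: Sequence[Track], spec: RenderSpec,
                 seed: int | None = None
                 ) -> tuple[np.ndarray, pd.DataFrame]:
    """Render tracks into a grayscale stack with per-frame ground truth.

    Cells are drawn as Gaussian spots (see :class:`RenderSpec`); the truth
    table lists every rendered cell per frame with pixel-frame centroid,
    area in px² and a ``stuck`` flag for motionless decoys.
    """
    if not tracks:
        raise ValueError("cannot render an empty track list")
    rng = np.random.default_rng(seed)
    h, w = spec.shape
    n_frames = int(max(tr.frame.max() for tr in tracks)) + 1

    # motionless decoy cells, parked at random positions
    n_stuck = int(round(spec.stuck_fraction * len(tracks)))
    stuck = [(rng.uniform(0, w - 1), rng.uniform(0, h - 1),
              rng.uniform(0.3, 0.8)) for _ in range(n_stuck)]

    yy, xx = np.mgrid[0:h, 0:w]
    gx = (np.arange(w) / max(w - 1, 1))[None, :]
    gradient = spec.gradient_amplitude * np.broadcast_to(gx, (h, w))

    frames = np.zeros((n_frames, h, w), dtype=float)
    frames += spec.background + gradient
    rows = []

    def draw(frame_img, x_px, y_px, radius_um):
        sig = spec.spot_sigma_px(radius_um)
        amp = spec.peak_amplitude(radius_um)
        x0, x1 = int(max(0, x_px - 5 * sig)), int(min(w, x_px + 5 * sig + 1))
        y0, y1 = int(max(0, y_px - 5 * sig)), int(min(h, y_px + 5 * sig + 1))
        if x0 >= x1 or y0 >= y1:
            return False
        sub_y = yy[y0:y1, x0:x1]
        sub_x = xx[y0:y1, x0:x1]
        frame_img[y0:y1, x0:x1] += amp * np.exp(
            -((sub_x - x_px) ** 2 + (sub_y - y_px) ** 2) / (2 * sig**2))
        return True

    any_visible = False
    for tr in tracks:
        x_px, y_px = um_to_px(tr.x_um, tr.y_um, spec.pixel_size_um)
        for k, f in enumerate(tr.frame):
            if not (0 <= x_px[k] <= w - 1 and 0 <= y_px[k] <= h - 1):
                continue
            radius = float(np.sqrt(tr.area_um2[k] / np.pi))
            if draw(frames[f], x_px[k], y_px[k], radius):
                any_visible = True
                rows.append({"frame": int(f), "cell_id": tr.track_id,
                             "x_px": float(x_px[k]), "y_px": float(y_px[k]),
                             "area_px2": float(tr.area_um2[k]
                                               / spec.pixel_size_um**2),
                             "r_um": radius, "stuck": False})
    if not any_visible:
        raise ValueError("no track point falls inside the field of view")

    for j, (sx, sy, srad) in enumerate(stuck):
        for f in range(n_frames):
            draw(frames[f], sx, sy, srad)
            rows.append({"frame": f, "cell_id": -(j + 1), "x_px": sx,
                         "y_px": sy,
                         "area_px2": np.pi * srad**2 / spec.pixel_size_um**2,
                         "r_um": srad, "stuck": True})

    if spec.poisson_noise:
        frames = rng.poisson(np.clip(frames, 0, None)).astype(float)
    if spec.read_noise > 0:
        frames += rng.normal(0, spec.read_noise, frames.shape)

    info = np.iinfo(np.dtype(spec.dtype))
    stack = np.clip(np.round(frames), info.min, info.max).astype(spec.dtype)
    truth = pd.DataFrame(rows).sort_values(["frame", "cell_id"],
                                           ignore_index=True)
    return stack, truth
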