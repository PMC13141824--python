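"""Population decomposition of heterogeneous MTB samples.

The statistical core: a smooth density surface (Epanechnikov product
kernel, Sheather–Jones bandwidths) is decomposed into a sum of scaled
bivariate Gaussians by differential evolution, the component count is
selected by the Akaike information criterion, and components are ranked
by their share of the reconstructed PDF volume.  Companion tools: the
error-weighted critical-radius fit, directional-quantile uncertainty
envelopes, and variational Gaussian-mixture clustering in (r, v, m).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from scipy.optimize import differential_evolution
from scipy.spatial import HalfspaceIntersection
from shapely.geometry import Polygon

from .bandwidth import sheather_jones, to_epanechnikov

logger = logging.getLogger(__name__)

__all__ = ["KDESurface", "MixtureComponent", "PopulationModel",
           "CriticalRadiusFit", "QuantileEnvelope", "kde2d",
           "fit_mixture", "fit_mixture_sweep", "significance_filter",
           "critical_radius", "quantile_envelope", "cluster_rvm",
           "RVMClusters"]


# --------------------------------------------------------------------------
# kernel density surface

@dataclass
class KDESurface:
    """Product-kernel density estimate on a regular grid.

    ``density[i, j]`` is the density at (x[i], y[j]); the grid integrates
    to ~1 (up to kernel mass falling outside the padded range).
    """

    density: np.ndarray
    x: np.ndarray
    y: np.ndarray
    bandwidth: tuple[float, float]

    @property
    def cell_area(self) -> float:
        return float((self.x[1] - self.x[0]) * (self.y[1] - self.y[0]))

    def integral(self) -> float:
        return float(self.density.sum() * self.cell_area)


def _epan_profile(grid: np.ndarray, pts: np.ndarray, h: float) -> np.ndarray:
    """(n_grid, n_points) Epanechnikov kernel matrix, K(u)=3/4(1-u^2)/h."""
    u = (grid[:, None] - pts[None, :]) / h
    out = 0.75 * (1.0 - u * u) / h
    np.clip(out, 0.0, None, out=out)
    return out


def kde2d(points: np.ndarray,
          bandwidth: Literal["auto"] | tuple[float, float] = "auto",
          grid_size: int = 128, pad: float = 1.0) -> KDESurface:
    """2D KDE with a product Epanechnikov kernel.

    ``bandwidth="auto"`` selects per-axis Sheather–Jones bandwidths
    (converted to the Epanechnikov half-support); explicit values are the
    kernel half-supports themselves.  The grid covers the data range
    padded by ``pad`` bandwidths so the estimate integrates to 1.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    n = len(pts)
    if n < 10:
        raise ValueError("need at least 10 points")
    if np.ptp(pts[:, 0]) == 0 or np.ptp(pts[:, 1]) == 0:
        raise ValueError("degenerate axis: all values identical")
    if bandwidth == "auto":
        hx = to_epanechnikov(sheather_jones(pts[:, 0]))
        hy = to_epanechnikov(sheather_jones(pts[:, 1]))
    else:
        hx, hy = bandwidth
        if hx <= 0 or hy <= 0:
            raise ValueError("bandwidths must be > 0")
    gx = np.linspace(pts[:, 0].min() - pad * hx, pts[:, 0].max() + pad * hx,
                     grid_size)
    gy = np.linspace(pts[:, 1].min() - pad * hy, pts[:, 1].max() + pad * hy,
                     grid_size)
    kx = _epan_profile(gx, pts[:, 0], hx)
    ky = _epan_profile(gy, pts[:, 1], hy)
    density = kx @ ky.T / n
    return KDESurface(density=density, x=gx, y=gy, bandwidth=(hx, hy))


# --------------------------------------------------------------------------
# scaled-Gaussian mixture fit of the density surface

@dataclass(frozen=True)
class MixtureComponent:
    """Scaled bivariate Gaussian: amplitude * exp(-q/2) with the full
    symmetric covariance [[s1^2, rho s1 s2], [rho s1 s2, s2^2]]."""

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    rho: float
    amplitude: float

    @property
    def volume(self) -> float:
        """Integral of the scaled Gaussian over the plane."""
        return float(self.amplitude * 2 * np.pi * self.sigma1 * self.sigma2
                     * np.sqrt(1 - self.rho**2))

    def evaluate(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        z1 = (X - self.mu1) / self.sigma1
        z2 = (Y - self.mu2) / self.sigma2
        q = (z1**2 - 2 * self.rho * z1 * z2 + z2**2) / (1 - self.rho**2)
        return self.amplitude * np.exp(-q / 2)


@dataclass
class PopulationModel:
    """AIC-selected mixture decomposition of a density surface."""

    components: list[MixtureComponent]
    n_components: int
    aic: float
    rss: float
    aic_by_n: dict[int, float] = field(default_factory=dict)
    shares: np.ndarray | None = None
    significant: np.ndarray | None = None

    def evaluate(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        return sum(c.evaluate(X, Y) for c in self.components)

    @property
    def n_significant(self) -> int:
        if self.significant is None:
            raise ValueError("run significance_filter first")
        return int(np.sum(self.significant))


def _mixture_objective(theta: np.ndarray, X: np.ndarray, Y: np.ndarray,
                       Z: np.ndarray, n_comp: int) -> np.ndarray:
    """Vectorized RSS for a (6*n_comp, S) batch of parameter vectors."""
    single = theta.ndim == 1
    th = theta[:, None] if single else theta
    S = th.shape[1]
    model = np.zeros((S, Z.size))
    for c in range(n_comp):
        mu1, mu2, s1, s2, rho, a = th[6 * c:6 * c + 6]
        z1 = (X[None, :] - mu1[:, None]) / s1[:, None]
        z2 = (Y[None, :] - mu2[:, None]) / s2[:, None]
        r = rho[:, None]
        q = (z1 * z1 - 2 * r * z1 * z2 + z2 * z2) / (1 - r * r)
        model += a[:, None] * np.exp(-q / 2)
    rss = np.sum((model - Z[None, :]) ** 2, axis=1)
    return rss[0] if single else rss


def _component_bounds(surface: KDESurface) -> list[tuple[float, float]]:
    xr = float(np.ptp(surface.x))
    yr = float(np.ptp(surface.y))
    zmax = float(surface.density.max())
    return [
        (surface.x.min() - 0.2 * xr, surface.x.max() + 0.2 * xr),
        (surface.y.min() - 0.2 * yr, surface.y.max() + 0.2 * yr),
        (xr / 200, xr), (yr / 200, yr),
        (-0.95, 0.95),
        (0.0, 1.5 * zmax),
    ]


def _warm_rows(surface: KDESurface, prev: list[MixtureComponent],
               bounds: list[tuple[float, float]], rng: np.random.Generator,
               n_rows: int) -> np.ndarray:
    """Candidate parameter vectors extending the best (n-1)-component fit.

    New components are planted at the peaks of the residual surface (and
    jittered), so differential evolution starts near the greedy solution
    instead of searching the full 6n-dimensional box blind.
    """
    X, Y = np.meshgrid(surface.x, surface.y, indexing="ij")
    resid = surface.density - sum(c.evaluate(X, Y) for c in prev)
    i, j = np.unravel_index(np.argmax(resid), resid.shape)
    hx, hy = surface.bandwidth
    base = []
    for c in prev:
        base.extend([c.mu1, c.mu2, c.sigma1, c.sigma2, c.rho, c.amplitude])
    new = [surface.x[i], surface.y[j], 2 * hx, 2 * hy, 0.0,
           max(float(resid[i, j]), 0.0)]
    vec = np.array(base + new)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    rows = np.clip(vec + rng.normal(0, 0.05, (n_rows, len(vec)))
                   * (hi - lo), lo, hi)
    rows[0] = np.clip(vec, lo, hi)
    return rows


def fit_mixture(surface: KDESurface, n_components: int, seed: int, *,
                popsize: int = 8, maxiter: int = 150, tol: float = 1e-10,
                warm_start: list[MixtureComponent] | None = None
                ) -> tuple[list[MixtureComponent], float]:
    """Least-squares fit of ``n_components`` scaled Gaussians to a surface
    by differential evolution (seeded, vectorized, L-BFGS-B polish).

    ``warm_start`` (the best fit with one component fewer) seeds part of
    the initial population.  Returns the components (sorted by volume,
    descending) and the RSS.
    """
    X, Y = np.meshgrid(surface.x, surface.y, indexing="ij")
    Xf, Yf, Zf = X.ravel(), Y.ravel(), surface.density.ravel()
    bounds = _component_bounds(surface) * n_components
    rng = np.random.default_rng(seed)
    dim = 6 * n_components
    n_pop = max(popsize * dim, 48)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    init = lo + (hi - lo) * rng.random((n_pop, dim))
    if warm_start is not None and len(warm_start) == n_components - 1:
        k = max(n_pop // 4, 4)
        init[:k] = _warm_rows(surface, warm_start, bounds, rng, k)
    result = differential_evolution(
        _mixture_objective, bounds, args=(Xf, Yf, Zf, n_components),
        seed=seed, maxiter=maxiter, tol=tol, init=init,
        vectorized=True, updating="deferred", polish=False)
    # Gauss-Newton refinement on the residual vector: far better
    # conditioned than a scalar polish of the RSS, and removes the
    # run-to-run scatter the population search leaves behind
    def _resid_vec(theta):
        model = np.zeros_like(Zf)
        for c in range(n_components):
            mu1, mu2, s1, s2, rho, a = theta[6 * c:6 * c + 6]
            z1 = (Xf - mu1) / s1
            z2 = (Yf - mu2) / s2
            q = (z1 * z1 - 2 * rho * z1 * z2 + z2 * z2) / (1 - rho * rho)
            model += a * np.exp(-q / 2)
        return model - Zf

    from scipy.optimize import least_squares

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    x0 = np.clip(result.x, lo + 1e-12, hi - 1e-12)
    refined = least_squares(_resid_vec, x0, bounds=(lo, hi), method="trf",
                            max_nfev=400)
    th, rss = refined.x, float(2 * refined.cost)
    if rss > result.fun:                      # keep the better of the two
        th, rss = result.x, float(result.fun)
    comps = [MixtureComponent(*th[6 * c:6 * c + 6])
             for c in range(n_components)]
    comps.sort(key=lambda c: c.volume, reverse=True)
    return comps, rss


def fit_mixture_sweep(data: KDESurface | np.ndarray,
                      n_range: Iterable[int] = range(1, 7),
                      seed: int = 0, *, grid_size: int = 56,
                      popsize: int = 8, maxiter: int = 150,
                      min_share: float = 0.05,
                      delta_aic: float = 2.0) -> PopulationModel:
    """AIC-constrained sweep over the number of mixture components.

    ``data`` may be raw (n, 2) points (a KDE surface is built first) or a
    ready surface.  For each n the surface is fitted by differential
    evolution; AIC = N ln(RSS/N) + 2k with N grid cells and k = 6n.  The
    minimum-AIC model wins, with ties broken toward the smallest n within
    ``delta_aic``.  The returned model already carries volume shares and
    significance flags (share >= ``min_share``).
    """
    if isinstance(data, KDESurface):
        surface = data
    else:
        surface = kde2d(np.asarray(data, dtype=float), grid_size=grid_size)
    N = surface.density.size
    rng = np.random.default_rng(seed)
    results: dict[int, tuple[list[MixtureComponent], float, float]] = {}
    prev_best: list[MixtureComponent] | None = None
    for n in sorted(n_range):
        sub_seed = int(rng.integers(2**31))
        try:
            comps, rss = fit_mixture(surface, n, sub_seed,
                                     popsize=popsize, maxiter=maxiter,
                                     warm_start=prev_best)
            prev_best = comps
        except Exception:                                 # noqa: BLE001
            logger.exception("mixture fit with n=%d failed; skipped", n)
            continue
        aic = N * np.log(max(rss, 1e-300) / N) + 2 * (6 * n)
        results[n] = (comps, rss, aic)
    if not results:
        raise RuntimeError("every mixture fit in the sweep failed")
    aic_by_n = {n: r[2] for n, r in results.items()}
    best_aic = min(aic_by_n.values())
    n_best = min(n for n, a in aic_by_n.items() if a - best_aic < delta_aic)
    comps, rss, aic = results[n_best]
    model = PopulationModel(components=comps, n_components=n_best,
                            aic=aic, rss=rss, aic_by_n=aic_by_n)
    return significance_filter(model, min_share=min_share)


def significance_filter(model: PopulationModel,
                        min_share: float = 0.05) -> PopulationModel:
    """Attach PDF-volume shares and flag components below ``min_share``.

    A component's share is its integrated volume a 2 pi s1 s2 sqrt(1-rho^2)
    over the total; shares sum to 1 before filtering.
    """
    vols = np.array([c.volume for c in model.components], dtype=float)
    total = vols.sum()
    shares = vols / total if total > 0 else np.zeros_like(vols)
    model.shares = shares
    model.significant = shares >= min_share
    return model


# --------------------------------------------------------------------------
# error-weighted critical radius

@dataclass(frozen=True)
class CriticalRadiusFit:
    """Error-weighted linear model m = b0 + b1 R and its zero crossing
    r_c = -b0/b1 (the radius below which no measurable moment fits)."""

    slope: float
    intercept: float
    r_c: float
    slope_se: float
    intercept_se: float
    r_c_se: float
    valid: bool


def critical_radius(radius_um: np.ndarray, moment: np.ndarray,
                    sigma_m: np.ndarray) -> CriticalRadiusFit:
    """Weighted least squares of moment on radius, weights 1/sigma_m^2.

    The critical radius r_c = -b0/b1 carries a delta-method standard
    error.  A non-positive slope leaves r_c undefined (``valid=False``).
    """
    r = np.asarray(radius_um, dtype=float)
    m = np.asarray(moment, dtype=float)
    s = np.asarray(sigma_m, dtype=float)
    if len(r) < 3:
        raise ValueError("need at least 3 points")
    if np.any(s <= 0):
        raise ValueError("sigma_m must be > 0")
    w = 1.0 / s**2
    A = np.column_stack([np.ones_like(r), r])
    AtW = A.T * w
    cov = np.linalg.inv(AtW @ A)
    b0, b1 = cov @ (AtW @ m)
    se0, se1 = np.sqrt(np.diag(cov))
    if b1 <= 0:
        return CriticalRadiusFit(b1, b0, np.nan, se1, se0, np.nan, False)
    r_c = -b0 / b1
    g = np.array([-1.0 / b1, b0 / b1**2])  # d r_c / d(b0, b1)
    r_c_se = float(np.sqrt(g @ cov @ g))
    return CriticalRadiusFit(float(b1), float(b0), float(r_c),
                             float(se1), float(se0), r_c_se, True)


# --------------------------------------------------------------------------
# directional quantile envelope

@dataclass
class QuantileEnvelope:
    """Convex q-quantile uncertainty region from directional projections."""

    q: float
    n_directions: int
    vertices: np.ndarray          # (k, 2), closed implicitly

    def contains(self, points: np.ndarray) -> np.ndarray:
        poly = Polygon(self.vertices)
        from shapely.geometry import Point

        pts = np.atleast_2d(points)
        return np.array([poly.covers(Point(*p)) for p in pts])

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


def quantile_envelope(points: np.ndarray, q: float = 0.95,
                      n_directions: int = 250,
                      simplify_tol: float | None = None) -> QuantileEnvelope:
    """Intersection of half-planes at the q-quantile of projections onto
    ``n_directions`` evenly spaced directions, Douglas–Peucker simplified.

    With ``q=1`` the region contains the whole sample (and hence its
    convex hull).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 20:
        raise ValueError("need an (n>=20, 2) point array")
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    center = pts.mean(axis=0)
    centered = pts - center
    angles = 2 * np.pi * np.arange(n_directions) / n_directions
    U = np.column_stack([np.cos(angles), np.sin(angles)])
    proj = centered @ U.T                                # (n, n_directions)
    if q == 1:
        offs = proj.max(axis=0)
    else:
        offs = np.quantile(proj, q, axis=0)
    # guarantee a feasible interior point for the half-space intersection
    eps = 1e-9 * max(np.abs(offs).max(), 1.0)
    offs = np.maximum(offs, eps)
    halfspaces = np.column_stack([U, -offs])             # u.x - off <= 0
    hs = HalfspaceIntersection(halfspaces, np.zeros(2))
    verts = hs.intersections + center
    order = np.argsort(np.arctan2(verts[:, 1] - center[1],
                                  verts[:, 0] - center[0]))
    verts = verts[order]
    if simplify_tol is None:
        diam = float(np.hypot(*(verts.max(axis=0) - verts.min(axis=0))))
        simplify_tol = 0.002 * diam
    poly = Polygon(verts).simplify(simplify_tol, preserve_topology=True)
    if simplify_tol > 0:
        # simplification cuts corners inward; a mitred outward buffer keeps
        # the polygon a (slightly conservative) superset of the exact region
        poly = poly.buffer(simplify_tol, join_style=2)
        poly = poly.simplify(simplify_tol / 10, preserve_topology=True)
    out = np.asarray(poly.exterior.coords)[:-1]
    return QuantileEnvelope(q=q, n_directions=n_directions, vertices=out)


# --------------------------------------------------------------------------
# variational clustering in (r, v, m)

@dataclass
class RVMClusters:
    """Variational Gaussian-mixture clustering of (r, v, m) points."""

    labels: np.ndarray
    means: np.ndarray             # (k_effective, 3), original units
    weights: np.ndarray           # per effective cluster
    n_effective: int


def cluster_rvm(points: np.ndarray, max_components: int = 8,
                seed: int = 0, weight_floor: float = 0.01) -> RVMClusters:
    """Variational Bayesian GMM with a Dirichlet-process weight prior.

    Features are standardized internally (r, v and m live on wildly
    different scales); clusters whose posterior weight exceeds
    ``weight_floor`` count as effective.  Fixed seed => reproducible.
    """
    from sklearn.mixture import BayesianGaussianMixture

    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (n, 3): (r, v, m)")
    if len(pts) < 10 * max_components:
        raise ValueError("need at least 10 points per allowed component")
    mu = pts.mean(axis=0)
    sd = pts.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("singular data: a feature is constant")
    z = (pts - mu) / sd
    bgm = BayesianGaussianMixture(
        n_components=max_components,
        weight_concentration_prior_type="dirichlet_process",
        covariance_type="full", max_iter=500, random_state=seed)
    labels = bgm.fit_predict(z)
    eff = np.flatnonzero(bgm.weights_ > weight_floor)
    # restrict to clusters that actually own points
    eff = np.array([k for k in eff if np.any(labels == k)], dtype=int)
    means = bgm.means_[eff] * sd + mu
    return RVMClusters(labels=labels, means=means,
                       weights=bgm.weights_[eff], n_effective=len(eff))
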