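"""Statistical core: bandwidth selection, KDE surfaces, mixture sweep,
significance shares, critical radius, envelopes, and (r, v, m) clustering."""

import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pytest

from magnetokinetics.bandwidth import sheather_jones, to_epanechnikov
from magnetokinetics.populations import (cluster_rvm, critical_radius,
                                         fit_mixture_sweep, kde2d,
                                         quantile_envelope,
                                         significance_filter,
                                         MixtureComponent, PopulationModel)
from magnetokinetics.synthetic import GaussianComponent, \
    sample_component_points


class TestSheatherJones:
    def test_agrees_with_reference_implementation(self):
        """Cross-check against R's bw.SJ(method='ste') on the same draw."""
        rng = np.random.default_rng(42)
        x = rng.standard_normal(800)
        with tempfile.TemporaryDirectory() as td:
            path = Path(td) / "x.txt"
            np.savetxt(path, x)
            out = subprocess.run(
                ["Rscript", "-e",
                 f'cat(bw.SJ(scan("{path}", quiet=TRUE), method="ste"))'],
                capture_output=True, text=True, check=True)
        h_ref = float(out.stdout.strip())
        assert sheather_jones(x) == pytest.approx(h_ref, rel=0.03)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2000)
        assert sheather_jones(3.5 * x) == pytest.approx(
            3.5 * sheather_jones(x), rel=0.02)

    def test_epanechnikov_conversion_factor(self):
        assert to_epanechnikov(1.0) == pytest.approx(2.2138)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            sheather_jones(np.ones(100))


class TestKDE2D:
    def test_grid_integrates_to_one(self):
        rng = np.random.default_rng(0)
        surf = kde2d(rng.standard_normal((10000, 2)))
        assert surf.integral() == pytest.approx(1.0, abs=1e-3)

    def test_mode_at_tight_cluster_mean(self):
        rng = np.random.default_rng(1)
        pts = rng.normal([2.0, -1.0], 0.05, (2000, 2))
        surf = kde2d(pts)
        i, j = np.unravel_index(surf.density.argmax(), surf.density.shape)
        # the KDE mode scatters around the sample mean within a bandwidth
        hx, hy = surf.bandwidth
        assert abs(surf.x[i] - pts[:, 0].mean()) <= hx
        assert abs(surf.y[j] - pts[:, 1].mean()) <= hy

    def test_l1_close_to_true_standard_normal(self):
        rng = np.random.default_rng(2)
        surf = kde2d(rng.standard_normal((10000, 2)))
        X, Y = np.meshgrid(surf.x, surf.y, indexing="ij")
        truth = np.exp(-(X**2 + Y**2) / 2) / (2 * np.pi)
        l1 = np.abs(surf.density - truth).sum() * surf.cell_area
        assert l1 < 0.1

    def test_degenerate_axis_rejected(self):
        pts = np.column_stack([np.ones(100), np.arange(100.0)])
        with pytest.raises(ValueError):
            kde2d(pts)


class TestMixtureSweep:
    def test_single_population_recovered(self):
        comp = GaussianComponent(1.0, 0.5, 0.3, 0.08, 0.2)
        pts = sample_component_points([comp], 20000, seed=0)
        model = fit_mixture_sweep(pts, n_range=range(1, 4), seed=0,
                                  grid_size=48, maxiter=100)
        assert model.n_significant == 1
        c = model.components[int(np.flatnonzero(model.significant)[0])]
        assert c.mu1 == pytest.approx(comp.mu1, abs=0.05 * comp.sigma1 * 5)
        assert c.mu2 == pytest.approx(comp.mu2, abs=0.05 * comp.sigma2 * 5)
        assert c.sigma1 == pytest.approx(comp.sigma1, rel=0.08)
        assert c.sigma2 == pytest.approx(comp.sigma2, rel=0.08)
        assert np.sign(c.rho) == np.sign(comp.rho)

    def test_two_separated_populations_found(self):
        comps = [GaussianComponent(0.6, 0.35, 0.12, 0.04, 0.0),
                 GaussianComponent(1.5, 0.7, 0.12, 0.05, 0.0)]
        pts = sample_component_points(comps, 30000, seed=1)
        model = fit_mixture_sweep(pts, n_range=range(1, 4), seed=1,
                                  grid_size=48, maxiter=100)
        assert model.n_significant == 2

    def test_deterministic_under_seed(self):
        comp = GaussianComponent(1.0, 0.5, 0.2, 0.05, 0.0)
        pts = sample_component_points([comp], 5000, seed=3)
        m1 = fit_mixture_sweep(pts, n_range=[1], seed=9, grid_size=40)
        m2 = fit_mixture_sweep(pts, n_range=[1], seed=9, grid_size=40)
        assert m1.components[0] == m2.components[0]


class TestSignificance:
    def test_equal_components_equal_shares(self):
        comps = [MixtureComponent(0, 0, 1, 1, 0.0, 2.0),
                 MixtureComponent(5, 5, 1, 1, 0.0, 2.0)]
        model = significance_filter(
            PopulationModel(comps, 2, 0.0, 0.0))
        assert np.allclose(model.shares, [0.5, 0.5])
        assert model.shares.sum() == pytest.approx(1.0)

    def test_zero_amplitude_component_not_significant(self):
        comps = [MixtureComponent(0, 0, 1, 1, 0.0, 2.0),
                 MixtureComponent(5, 5, 1, 1, 0.0, 0.0)]
        model = significance_filter(PopulationModel(comps, 2, 0.0, 0.0))
        assert model.shares[1] == 0.0
        assert model.n_significant == 1

    def test_small_component_flagged_like_day2_dashed_ellipse(self):
        # one fitted component holding <5% of the PDF volume is reported
        # but flagged non-significant
        comps = [MixtureComponent(0, 0, 1, 1, 0.0, 1.0),
                 MixtureComponent(2, 2, 1, 1, 0.0, 1.0),
                 MixtureComponent(4, 4, 0.5, 0.5, 0.0, 0.05)]
        model = significance_filter(PopulationModel(comps, 3, 0.0, 0.0))
        assert list(model.significant) == [True, True, False]


class TestCriticalRadius:
    def test_exact_line_recovers_intercept(self):
        R = np.linspace(0.3, 1.2, 40)
        m = 5e-15 * (R - 0.57)
        fit = critical_radius(R, m, np.full_like(R, 1e-16))
        assert fit.valid
        assert fit.r_c == pytest.approx(0.57, abs=1e-9)

    def test_equal_weights_match_ols(self):
        rng = np.random.default_rng(0)
        R = rng.uniform(0.3, 1.2, 60)
        m = 4e-15 * (R - 0.5) + rng.normal(0, 2e-16, 60)
        wls = critical_radius(R, m, np.full_like(R, 1e-16))
        b1, b0 = np.polyfit(R, m, 1)
        assert wls.slope == pytest.approx(b1)
        assert wls.intercept == pytest.approx(b0)

    def test_monte_carlo_bias_below_standard_error(self):
        rng = np.random.default_rng(1)
        r_cs, ses = [], []
        for _ in range(100):
            R = rng.uniform(0.3, 1.2, 120)
            sigma = rng.uniform(1e-16, 4e-16, 120)
            m = 5e-15 * (R - 0.57) + rng.normal(0, sigma)
            fit = critical_radius(R, m, sigma)
            r_cs.append(fit.r_c)
            ses.append(fit.r_c_se)
        bias = abs(np.mean(r_cs) - 0.57)
        assert bias < np.mean(ses)
        # the reported SE matches the observed spread
        assert np.std(r_cs) == pytest.approx(np.mean(ses), rel=0.3)

    def test_negative_slope_flagged_invalid(self):
        R = np.linspace(0.3, 1.2, 20)
        fit = critical_radius(R, -1e-15 * R, np.full_like(R, 1e-16))
        assert not fit.valid
        assert np.isnan(fit.r_c)


class TestQuantileEnvelope:
    def test_isotropic_gaussian_gives_q_circle(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((20000, 2))
        env = quantile_envelope(pts, q=0.95, n_directions=250)
        radii = np.hypot(*(env.vertices - pts.mean(axis=0)).T)
        assert radii.mean() == pytest.approx(1.645, rel=0.05)
        assert radii.max() / radii.min() < 1.1

    def test_q_one_contains_convex_hull(self):
        rng = np.random.default_rng(4)
        pts = rng.standard_normal((400, 2)) @ np.array([[2.0, 0.5],
                                                        [0.0, 1.0]])
        env = quantile_envelope(pts, q=1.0)
        assert env.contains(pts).all()

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((5000, 2)) * [3.0, 1.0]
        th = 0.6
        R = np.array([[np.cos(th), -np.sin(th)],
                      [np.sin(th), np.cos(th)]])
        a_about = quantile_envelope(pts, q=0.9).polygon.area
        a_rot = quantile_envelope(pts @ R.T, q=0.9).polygon.area
        assert a_rot == pytest.approx(a_about, rel=0.02)


class TestClusterRVM:
    def test_three_separated_blobs(self):
        rng = np.random.default_rng(6)
        pts = np.vstack([
            rng.normal([0.5, 10.0, 1e-15], [0.04, 1.0, 1e-16], (300, 3)),
            rng.normal([0.8, 30.0, 2e-15], [0.04, 2.0, 2e-16], (300, 3)),
            rng.normal([1.1, 20.0, 5e-15], [0.04, 2.0, 3e-16], (300, 3))])
        cl = cluster_rvm(pts, max_components=8, seed=0)
        assert cl.n_effective == 3

    def test_single_blob_pruned_to_one(self):
        rng = np.random.default_rng(7)
        pts = rng.normal([0.8, 20.0, 2e-15], [0.05, 2.0, 2e-16], (400, 3))
        cl = cluster_rvm(pts, max_components=8, seed=0)
        assert cl.n_effective == 1

    def test_cluster_count_invariant_to_row_permutation(self):
        rng = np.random.default_rng(8)
        pts = np.vstack([
            rng.normal([0.5, 10.0, 1e-15], [0.04, 1.0, 1e-16], (200, 3)),
            rng.normal([1.1, 30.0, 5e-15], [0.04, 2.0, 3e-16], (200, 3))])
        a = cluster_rvm(pts, max_components=6, seed=1)
        b = cluster_rvm(pts[rng.permutation(len(pts))], max_components=6,
                        seed=1)
        assert a.n_effective == b.n_effective
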