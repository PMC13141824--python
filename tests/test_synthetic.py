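"""Generators: population sampling, U-turn datasets, stack rendering."""

import numpy as np
import pytest

import magnetokinetics as mk
from magnetokinetics.synthetic import (DAY1_VELOCIMETRY_COMPONENTS,
                                       GaussianComponent, PopulationSpec,
                                       RenderSpec, gen_uturn_dataset,
                                       render_stack, sample_component_points,
                                       sample_population)
from .conftest import FIELD_T


class TestSamplePopulation:
    def test_single_component_moments_converge(self):
        comp = GaussianComponent(1.2, 0.6, 0.2, 0.2, 0.0)
        spec = PopulationSpec(components=(comp,), n_cells=4000,
                              min_radius=1e-6)
        cells = sample_population(spec, seed=0)
        logv = np.log10([c.speed for c in cells])
        r = np.array([c.radius for c in cells])
        assert logv.mean() == pytest.approx(1.2, abs=3 * 0.2 / np.sqrt(4000))
        assert r.mean() == pytest.approx(0.6, abs=3 * 0.2 / np.sqrt(4000))

    def test_reference_day1_rows_reproduced(self):
        pts = sample_component_points(DAY1_VELOCIMETRY_COMPONENTS, 40000,
                                      seed=1)
        # pooled first moment equals the weight-averaged component means
        mu1 = np.mean([c.mu1 for c in DAY1_VELOCIMETRY_COMPONENTS])
        mu2 = np.mean([c.mu2 for c in DAY1_VELOCIMETRY_COMPONENTS])
        assert pts[:, 0].mean() == pytest.approx(mu1, abs=0.01)
        assert pts[:, 1].mean() == pytest.approx(mu2, abs=0.005)

    def test_per_component_moments_match_generating_row(self):
        comp = DAY1_VELOCIMETRY_COMPONENTS[0]
        pts = sample_component_points([comp], 30000, seed=3)
        assert pts[:, 0].mean() == pytest.approx(comp.mu1, abs=0.01)
        assert pts[:, 0].std() == pytest.approx(comp.sigma1, rel=0.03)
        assert pts[:, 1].std() == pytest.approx(comp.sigma2, rel=0.03)
        rho = np.corrcoef(pts.T)[0, 1]
        assert rho == pytest.approx(comp.rho, abs=0.03)

    def test_zero_weight_component_never_drawn(self):
        comps = (GaussianComponent(1.0, 0.4, 0.1, 0.05, 0.0, weight=1.0),
                 GaussianComponent(9.0, 9.0, 0.1, 0.05, 0.0, weight=0.0))
        cells = sample_population(PopulationSpec(components=comps,
                                                 n_cells=500), seed=2)
        assert max(np.log10(c.speed) for c in cells) < 3.0

    def test_linear_moment_law_clips_below_critical_radius(self):
        spec = PopulationSpec(n_cells=800, moment_model="linear")
        cells = sample_population(spec, seed=5)
        for c in cells:
            if c.radius <= spec.critical_radius:
                assert c.moment == 0.0
            else:
                assert c.moment == pytest.approx(
                    spec.moment_slope * (c.radius - spec.critical_radius))

    def test_seed_reproducibility(self):
        spec = PopulationSpec(n_cells=100)
        a = sample_population(spec, seed=11)
        b = sample_population(spec, seed=11)
        assert all(x.speed == y.speed and x.radius == y.radius
                   for x, y in zip(a, b))


class TestGenUTurnDataset:
    def test_one_track_per_cell_with_truth(self):
        spec = PopulationSpec(n_cells=6)
        field = mk.FieldProtocol.square_wave(FIELD_T, 0.6, 3)
        tracks, truth = gen_uturn_dataset(spec, field, dt=0.02, seed=0)
        assert len(tracks) == 6
        assert len(truth) == 6
        assert set(truth.columns) >= {"cell_id", "v_um_s", "r_um", "m_Am2",
                                      "L_theory_um"}

    def test_requires_square_wave(self):
        with pytest.raises(ValueError):
            gen_uturn_dataset(PopulationSpec(n_cells=2),
                              mk.FieldProtocol(magnitude=FIELD_T), seed=0)

    def test_nonmagnetic_cells_ignore_reversals(self):
        comp = GaussianComponent(1.3, 0.4, 0.05, 0.02, 0.0)
        spec = PopulationSpec(components=(comp,), n_cells=3,
                              moment_model="linear")  # r < r_c -> m = 0
        field = mk.FieldProtocol.square_wave(FIELD_T, 0.5, 2)
        tracks, truth = gen_uturn_dataset(spec, field, dt=0.02, seed=1)
        assert (truth["m_Am2"] == 0).all()
        for tr in tracks:
            d = np.hypot(tr.x_um[-1] - tr.x_um[0], tr.y_um[-1] - tr.y_um[0])
            assert d == pytest.approx(tr.mean_speed() * tr.duration,
                                      rel=1e-6)

    def test_truth_width_matches_measured_lateral_width(self):
        comp = GaussianComponent(np.log10(30.0), 0.7, 1e-4, 1e-4, 0.0)
        spec = PopulationSpec(components=(comp,), n_cells=1,
                              moment_model="gaussian",
                              moment_mean=(1.5e-15,), moment_sd=(1e-22,))
        field = mk.FieldProtocol.square_wave(FIELD_T, 1.0, 2)
        tracks, truth = gen_uturn_dataset(spec, field, dt=0.02, seed=4)
        tr = tracks[0]
        leg1 = tr.y_um[(tr.t > 0.85) & (tr.t < 1.0)].mean()
        leg2 = tr.y_um[(tr.t > 1.85) & (tr.t < 2.0)].mean()
        assert abs(leg2 - leg1) == pytest.approx(
            truth["L_theory_um"].iloc[0], rel=0.01)


class TestRenderStack:
    def test_static_cell_no_noise_identical_frames(self):
        tr = mk.Track(0, np.arange(5), np.arange(5) * 0.02,
                      np.full(5, 20.0), np.full(5, -20.0),
                      np.full(5, np.pi * 0.5**2))
        stack, truth = render_stack([tr], RenderSpec(shape=(128, 128)),
                                    seed=0)
        assert np.array_equal(stack[0], stack[1])
        assert len(truth) == 5

    def test_isolated_spot_centroid_matches_truth(self):
        tr = mk.Track(0, [0], [0.0], [16.37], [-12.81], [np.pi * 0.6**2])
        spec = RenderSpec(shape=(128, 128), pixel_size_um=0.25)
        stack, truth = render_stack([tr], spec, seed=0)
        img = stack[0].astype(float) - spec.background
        yy, xx = np.mgrid[0:128, 0:128]
        cx = (img * xx).sum() / img.sum()
        cy = (img * yy).sum() / img.sum()
        assert cx == pytest.approx(truth.x_px.iloc[0], abs=0.1)
        assert cy == pytest.approx(truth.y_px.iloc[0], abs=0.1)

    def test_gradient_is_nuisance_only(self):
        tr = mk.Track(0, np.arange(3), np.arange(3) * 0.02,
                      [10.0, 10.5, 11.0], [-10.0, -10.0, -10.0],
                      np.full(3, 1.0))
        _, t1 = render_stack([tr], RenderSpec(gradient_amplitude=10.0),
                             seed=1)
        _, t2 = render_stack([tr], RenderSpec(gradient_amplitude=20.0),
                             seed=1)
        assert t1.equals(t2)

    def test_empty_track_list_rejected(self):
        with pytest.raises(ValueError):
            render_stack([], RenderSpec(), seed=0)

    def test_seeded_noise_reproducible(self):
        tr = mk.Track(0, np.arange(3), np.arange(3) * 0.02,
                      [10.0, 11.0, 12.0], [-10.0] * 3, np.full(3, 1.0))
        spec = RenderSpec(read_noise=5.0, poisson_noise=True)
        s1, _ = render_stack([tr], spec, seed=9)
        s2, _ = render_stack([tr], spec, seed=9)
        assert np.array_equal(s1, s2)
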