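"""Shared fixtures: simulated tracks and rendered scenes with ground truth."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import magnetokinetics as mk

settings.register_profile("suite", derandomize=True)
settings.load_profile("suite")
from magnetokinetics.physics import relaxation_time
from magnetokinetics.synthetic import PopulationSpec, RenderSpec, \
    render_stack, sample_population

#: experiment constants used throughout
FIELD_T = 2.55e-4
VISCOSITY = 0.90e-3


@pytest.fixture(scope="session")
def square_wave():
    return mk.FieldProtocol.square_wave(FIELD_T, half_period=1.0,
                                        n_reversals=4)


@pytest.fixture(scope="session")
def uturn_track(square_wave):
    """Noise-free Bean-model track with four U-turns (m = 1.5e-15 A·m²)."""
    cell = mk.CellState(speed=30.0, moment=1.5e-15, radius=0.7)
    return mk.simulate_trajectory(cell, square_wave, dt=0.02, duration=4.5)


@pytest.fixture(scope="session")
def straight_scene():
    """Straight-swimming cells rendered into a clean + a noisy stack.

    Returns (clean stack, noisy stack, truth table, render spec, tracks).
    """
    rng = np.random.default_rng(7)
    cells = sample_population(PopulationSpec(n_cells=18), seed=7)
    field = mk.FieldProtocol(magnitude=0.0)
    tracks = []
    for i, c in enumerate(cells):
        cell = mk.CellState(position=(rng.uniform(8, 56),
                                      rng.uniform(-56, -8)),
                            heading=rng.uniform(0, 2 * np.pi),
                            speed=min(c.speed, 40.0), moment=0.0,
                            radius=float(np.clip(c.radius, 0.35, 0.9)))
        tracks.append(mk.simulate_trajectory(cell, field, dt=0.02,
                                             duration=0.8, track_id=i))
    clean_spec = RenderSpec(shape=(256, 256), pixel_size_um=0.25)
    noisy_spec = RenderSpec(shape=(256, 256), pixel_size_um=0.25,
                            read_noise=10.0, poisson_noise=True,
                            gradient_amplitude=30.0)
    clean, truth = render_stack(tracks, clean_spec, seed=8)
    noisy, _ = render_stack(tracks, noisy_spec, seed=8)
    return clean, noisy, truth, noisy_spec, tracks


def detection_scores(detections, truth, tol_px=2.0):
    """Precision/recall of per-frame detections against ground truth."""
    tp = fp = fn = 0
    for f in range(len(detections)):
        g = truth[truth.frame == f]
        used = set()
        for d in detections[f]:
            dd = np.hypot(g.x_px.values - d.x_px, g.y_px.values - d.y_px)
            ok = [j for j in np.argsort(dd)
                  if dd[j] <= tol_px and j not in used]
            if ok:
                used.add(ok[0])
                tp += 1
            else:
                fp += 1
        fn += len(g) - len(used)
    return tp / max(tp + fp, 1), tp / max(tp + fn, 1)


def uturn_protocol_for(moment, radius, speed=25.0, n_reversals=3):
    """A square wave + sampling interval that resolves this cell's turns."""
    tau = relaxation_time(moment, radius, FIELD_T, VISCOSITY)
    half = max(14 * tau, 0.4)
    dt = min(half / 40, tau / 2)
    return mk.FieldProtocol.square_wave(FIELD_T, half, n_reversals), dt, half
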