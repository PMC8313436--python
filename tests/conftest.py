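"""Shared fixtures: phantoms, beam model, and small planning instances.

Everything is generated programmatically; session scope keeps the
expensive pieces (influence matrices, optimized plans) to one build.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import sparse

from sparclet.beam_physics import BeamModel, Spot, place_spots
from sparclet.influence import InfluencePair, compute_influence
from sparclet.optimize import ObjectiveSet, ObjectiveTerm, init_weights, solve_weights
from sparclet.phantoms import build_phantom, scenario_spec


@pytest.fixture(scope="session")
def model():
    return BeamModel()


@pytest.fixture(scope="session")
def prostate():
    spec = scenario_spec("prostate-like")
    phantom, rois = build_phantom(spec)
    return spec, phantom, {r.name: r for r in rois}


@pytest.fixture(scope="session")
def liver():
    spec = scenario_spec("liver-like")
    phantom, rois = build_phantom(spec)
    return spec, phantom, {r.name: r for r in rois}


@pytest.fixture(scope="session")
def brain():
    spec = scenario_spec("brain-like")
    phantom, rois = build_phantom(spec)
    return spec, phantom, {r.name: r for r in rois}


def random_influence(
    n_vox: int = 1000, n_spots: int = 20, density: float = 0.3, seed: int = 0
) -> InfluencePair:
    """Randomized synthetic influence pair for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    mask = rng.random((n_vox, n_spots)) < density
    d = np.where(mask, rng.random((n_vox, n_spots)), 0.0)
    l = np.where(mask, 0.5 + 10.0 * rng.random((n_vox, n_spots)), 0.0)
    D = sparse.csc_matrix(d)
    L = sparse.csc_matrix(l)
    return InfluencePair(D, L, np.arange(n_vox), (n_vox, 1, 1))


@pytest.fixture()
def rand_inf():
    return random_influence()


@pytest.fixture(scope="session")
def two_beam_instance(prostate, model):
    """Opposed-lateral spot set + influence on the prostate-like phantom."""
    _, phantom, rois = prostate
    angles = [90.0, 270.0]
    spots = []
    for k, ang in enumerate(angles):
        _, local = place_spots(phantom, rois["ctv"], ang, model, cp_index=k)
        spots.extend(local)
    inf = compute_influence(phantom, spots, angles, model)
    return phantom, rois, angles, spots, inf


@pytest.fixture(scope="session")
def prostate_objectives():
    return ObjectiveSet([
        ObjectiveTerm("ctv", "dose", "uniform", 78.0, 100.0),
        ObjectiveTerm("oar_left", "dose", "max", 60.0, 20.0),
        ObjectiveTerm("oar_right", "dose", "max", 60.0, 20.0),
        ObjectiveTerm("ctv", "letd", "min", 8.0, 60.0),
    ])


@pytest.fixture(scope="session")
def two_beam_solution(two_beam_instance, prostate_objectives):
    """Optimized weights for the opposed-lateral instance (dose-led start)."""
    phantom, rois, angles, spots, inf = two_beam_instance
    w0 = init_weights(inf, rois, "ctv", 78.0)
    w1, _ = solve_weights(
        inf, prostate_objectives.with_let_penalties_zeroed(), rois, w0
    )
    w, report = solve_weights(inf, prostate_objectives, rois, w1)
    return w, report
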