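"""Objective evaluation, exact gradients, solver, deliverable post-processing."""

import itertools

import numpy as np
import pytest
from scipy import sparse

from conftest import random_influence
from sparclet._errors import ConfigurationError, ContractViolation, PlanningError
from sparclet.influence import InfluencePair, accumulate_dose, accumulate_letd
from sparclet.optimize import (
    ObjectiveSet,
    ObjectiveTerm,
    deliverable_postprocess,
    init_weights,
    objective_gradient,
    objective_value,
    solve_weights,
    tune_let_penalties,
)
from sparclet.phantoms import ROIMask


def make_rois(shape, *specs):
    """ROI dict from (name, kind, slice-of-flat-indices) specs."""
    rois = {}
    n = int(np.prod(shape))
    for name, kind, sl in specs:
        mask = np.zeros(n, dtype=bool)
        mask[sl] = True
        rois[name] = ROIMask(name, mask.reshape(shape), kind)
    return rois


@pytest.fixture()
def toy():
    """Single-voxel, single-spot instance with D = 1 Gy/MU."""
    D = sparse.csc_matrix(np.array([[1.0]]))
    L = sparse.csc_matrix(np.array([[2.0]]))
    inf = InfluencePair(D, L, np.array([0]), (1, 1, 1))
    rois = make_rois((1, 1, 1), ("t", "target", slice(0, 1)))
    return inf, rois


class TestObjectiveValue:
    def test_hand_computed_quadratic(self, toy):
        inf, rois = toy
        objs = ObjectiveSet([ObjectiveTerm("t", "dose", "uniform", 2.0, 1.0)])
        # D_ij=1 Gy/MU, w=1 -> dose 1 Gy, goal 2 Gy, p=1 -> (1-2)^2 = 1
        assert objective_value(np.array([1.0]), objs, inf, rois) == pytest.approx(1.0)

    def test_exact_goal_gives_zero(self, toy):
        inf, rois = toy
        objs = ObjectiveSet([ObjectiveTerm("t", "dose", "uniform", 2.0, 5.0)])
        assert objective_value(np.array([2.0]), objs, inf, rois) == 0.0

    def test_oar_below_goal_contributes_nothing(self):
        inf = random_influence(n_vox=100, n_spots=6, seed=11)
        rois = make_rois(
            inf.shape, ("t", "target", slice(0, 50)), ("o", "oar", slice(50, 100))
        )
        objs_t = ObjectiveSet([ObjectiveTerm("t", "dose", "uniform", 1.0, 1.0)])
        objs_both = ObjectiveSet(
            [ObjectiveTerm("t", "dose", "uniform", 1.0, 1.0),
             ObjectiveTerm("o", "dose", "max", 1e9, 7.0)]
        )
        w = np.full(6, 0.3)
        assert objective_value(w, objs_both, inf, rois) == pytest.approx(
            objective_value(w, objs_t, inf, rois)
        )

    def test_objective_invariant_to_spot_permutation(self):
        inf = random_influence(n_vox=200, n_spots=8, seed=12)
        rois = make_rois(inf.shape, ("t", "target", slice(0, 120)))
        objs = ObjectiveSet(
            [ObjectiveTerm("t", "dose", "uniform", 1.0, 1.0),
             ObjectiveTerm("t", "letd", "min", 6.0, 2.0)]
        )
        rng = np.random.default_rng(13)
        w = rng.random(8)
        perm = rng.permutation(8)
        inf_p = InfluencePair(
            inf.D[:, perm].tocsc(), inf.L[:, perm].tocsc(), inf.voxel_index, inf.shape
        )
        assert objective_value(w[perm], objs, inf_p, rois) == pytest.approx(
            objective_value(w, objs, inf, rois), rel=1e-12
        )

    def test_unknown_roi_rejected(self, toy):
        inf, rois = toy
        objs = ObjectiveSet([ObjectiveTerm("nope", "dose", "uniform", 1.0, 1.0)])
        with pytest.raises(ConfigurationError):
            objective_value(np.array([1.0]), objs, inf, rois)

    def test_uniform_sense_requires_target(self):
        inf = random_influence(n_vox=50, n_spots=4, seed=14)
        rois = make_rois(inf.shape, ("t", "target", slice(0, 20)),
                         ("o", "oar", slice(20, 40)))
        objs = ObjectiveSet([ObjectiveTerm("o", "dose", "uniform", 1.0, 1.0)])
        with pytest.raises(ConfigurationError):
            objective_value(np.ones(4), objs, inf, rois)


def fd_gradient(f, w, eps=1e-6):
    g = np.zeros_like(w)
    for k in range(w.size):
        up, dn = w.copy(), w.copy()
        up[k] += eps
        dn[k] = max(dn[k] - eps, 0.0)
        g[k] = (f(up) - f(dn)) / (up[k] - dn[k])
    return g


class TestGradient:
    @pytest.mark.parametrize("with_let", [False, True])
    def test_matches_central_finite_differences(self, with_let):
        """Analytic gradient vs. central differences at 20 random points."""
        inf = random_influence(n_vox=400, n_spots=12, seed=15)
        rois = make_rois(
            inf.shape, ("t", "target", slice(0, 250)), ("o", "oar", slice(250, 400))
        )
        terms = [
            ObjectiveTerm("t", "dose", "uniform", 1.0, 1.0),
            ObjectiveTerm("o", "dose", "max", 0.4, 2.0),
        ]
        if with_let:
            terms += [
                ObjectiveTerm("t", "letd", "min", 7.0, 1.5),
                ObjectiveTerm("o", "letd", "max", 2.0, 1.5),
            ]
        objs = ObjectiveSet(terms)
        f = lambda w: objective_value(w, objs, inf, rois)
        rng = np.random.default_rng(16)
        for _ in range(20):
            w = 0.1 + rng.random(12)
            g = objective_gradient(w, objs, inf, rois)
            g_fd = fd_gradient(f, w)
            denom = max(np.linalg.norm(g_fd), 1e-12)
            assert np.linalg.norm(g - g_fd) / denom < 1e-6

    def test_let_terms_have_zero_directional_derivative_along_scaling(self):
        inf = random_influence(n_vox=300, n_spots=10, seed=17)
        rois = make_rois(inf.shape, ("t", "target", slice(0, 200)))
        objs = ObjectiveSet([ObjectiveTerm("t", "letd", "min", 7.0, 3.0)])
        rng = np.random.default_rng(18)
        w = 0.5 + rng.random(10)
        g = objective_gradient(w, objs, inf, rois)
        assert abs(float(g @ w)) < 1e-9 * max(1.0, np.linalg.norm(g) * np.linalg.norm(w))

    def test_zero_penalty_contributes_zero_gradient(self):
        inf = random_influence(n_vox=200, n_spots=8, seed=19)
        rois = make_rois(inf.shape, ("t", "target", slice(0, 150)))
        base = ObjectiveSet([ObjectiveTerm("t", "dose", "uniform", 1.0, 1.0)])
        extra = ObjectiveSet(
            base.terms + [ObjectiveTerm("t", "letd", "min", 7.0, 0.0)]
        )
        w = np.full(8, 0.7)
        assert np.allclose(
            objective_gradient(w, base, inf, rois),
            objective_gradient(w, extra, inf, rois),
        )


class TestSolver:
    def test_attainable_prescription_reaches_near_zero(self):
        # underdetermined instance: more spots than voxels, so the
        # prescription is exactly attainable and the optimum is ~0
        rng = np.random.default_rng(20)
        D = sparse.csc_matrix(0.5 + rng.random((2, 4)))
        L = sparse.csc_matrix(np.ones((2, 4)))
        inf = InfluencePair(D, L, np.arange(2), (2, 1, 1))
        rois = make_rois(inf.shape, ("t", "target", slice(0, 2)))
        objs = ObjectiveSet([ObjectiveTerm("t", "dose", "uniform", 10.0, 1.0)])
        w0 = init_weights(inf, rois, "t", 10.0)
        f0 = objective_value(w0, objs, inf, rois)
        w, rep = solve_weights(inf, objs, rois, w0)
        assert objective_value(w, objs, inf, rois) < 1e-3 * f0

    def test_three_spot_instance_matches_grid_search(self):
        """Solver within 1% of an exhaustive grid search over weights."""
        rng = np.random.default_rng(21)
        D = sparse.csc_matrix(rng.random((8, 3)))
        L = sparse.csc_matrix(1.0 + 5.0 * rng.random((8, 3)))
        inf = InfluencePair(D, L, np.arange(8), (8, 1, 1))
        rois = make_rois(inf.shape, ("t", "target", slice(0, 5)),
                         ("o", "oar", slice(5, 8)))
        objs = ObjectiveSet(
            [ObjectiveTerm("t", "dose", "uniform", 1.0, 1.0),
             ObjectiveTerm("o", "dose", "max", 0.5, 1.0),
             ObjectiveTerm("t", "letd", "min", 4.0, 0.5)]
        )
        grid = np.linspace(0.0, 2.0, 81)
        best = min(
            objective_value(np.array(c), objs, inf, rois)
            for c in itertools.product(grid, repeat=3)
        )
        w, _ = solve_weights(inf, objs, rois, np.full(3, 0.5))
        achieved = objective_value(w, objs, inf, rois)
        assert achieved <= best * 1.01 + 1e-12

    def test_start_at_optimum_returns_unchanged(self):
        D = sparse.csc_matrix(np.eye(4))
        L = sparse.csc_matrix(np.eye(4))
        inf = InfluencePair(D, L, np.arange(4), (4, 1, 1))
        rois = make_rois(inf.shape, ("t", "target", slice(0, 4)))
        objs = ObjectiveSet([ObjectiveTerm("t", "dose", "uniform", 3.0, 1.0)])
        w_opt = np.full(4, 3.0)
        w, rep = solve_weights(inf, objs, rois, w_opt)
        assert np.allclose(w, w_opt)
        assert rep.iterations <= 1

    def test_trace_non_increasing_and_final_below_initial(self, two_beam_solution):
        _, rep = two_beam_solution
        trace = rep.objective_trace
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))
        assert trace[-1] <= trace[0]

    def test_let_penalty_sweep_never_decreases_target_letd(self):
        inf = random_influence(n_vox=400, n_spots=10, seed=22)
        rois = make_rois(inf.shape, ("t", "target", slice(0, 300)))
        means = []
        for p in (0.0, 0.5, 2.0, 8.0):
            objs = ObjectiveSet(
                [ObjectiveTerm("t", "dose", "uniform", 1.0, 1.0),
                 ObjectiveTerm("t", "letd", "min", 8.0, p)]
            )
            w0 = init_weights(inf, rois, "t", 1.0)
            w1, _ = solve_weights(inf, objs.with_let_penalties_zeroed(), rois, w0)
            w, _ = solve_weights(inf, objs, rois, w1)
            rows = inf.rows_for_mask(rois["t"].mask)
            means.append(accumulate_letd(inf, w).values[rows].mean())
        assert all(b >= a - 1e-6 for a, b in zip(means, means[1:]))

    def test_dose_only_reduction_is_bitwise_reproducible(self, two_beam_instance,
                                                         prostate_objectives):
        phantom, rois, angles, spots, inf = two_beam_instance
        w0 = init_weights(inf, rois, "ctv", 78.0)
        dose_only = prostate_objectives.with_let_penalties_zeroed()
        w1, _ = solve_weights(inf, dose_only, rois, w0)
        w2, _ = solve_weights(inf, dose_only, rois, w0)
        assert np.array_equal(w1, w2)


class TestDeliverable:
    def _instance(self):
        rng = np.random.default_rng(23)
        D = sparse.csc_matrix(0.2 + rng.random((40, 12)))
        L = sparse.csc_matrix(np.ones((40, 12)))
        inf = InfluencePair(D, L, np.arange(40), (40, 1, 1))
        rois = make_rois(inf.shape, ("t", "target", slice(0, 40)))
        objs = ObjectiveSet([ObjectiveTerm("t", "dose", "uniform", 5.0, 1.0)])
        return inf, rois, objs

    def test_all_above_threshold_changes_little(self):
        inf, rois, objs = self._instance()
        w, _ = solve_weights(inf, objs, rois, init_weights(inf, rois, "t", 5.0))
        assert np.all((w == 0) | (w >= 0.02))
        f_before = objective_value(w, objs, inf, rois)
        wd, _ = deliverable_postprocess(w, inf, objs, rois, min_mu=0.02)
        f_after = objective_value(wd, objs, inf, rois)
        assert f_after <= max(f_before * 1.01, f_before + 1e-12)

    def test_subthreshold_spot_removed(self):
        inf, rois, objs = self._instance()
        w = np.full(12, 0.5)
        w[4] = 0.001
        wd, _ = deliverable_postprocess(w, inf, objs, rois, min_mu=0.02)
        assert wd[4] == 0.0
        nz = wd[wd > 0]
        assert np.all(nz >= 0.02)

    def test_gap_to_ideal_shrinks_with_min_mu(self):
        inf, rois, objs = self._instance()
        w, _ = solve_weights(inf, objs, rois, init_weights(inf, rois, "t", 5.0))
        dose_ideal = accumulate_dose(inf, w).values
        gaps = []
        for mu in (0.5, 0.1, 0.02):
            wd, _ = deliverable_postprocess(w, inf, objs, rois, min_mu=mu)
            gaps.append(np.abs(accumulate_dose(inf, wd).values - dose_ideal).max())
        assert gaps[0] >= gaps[1] >= gaps[2] - 1e-12

    def test_all_spots_removed_is_planning_failure(self):
        inf, rois, objs = self._instance()
        with pytest.raises(PlanningError):
            deliverable_postprocess(np.full(12, 0.001), inf, objs, rois, min_mu=0.02)


def test_tune_let_penalties_keeps_coverage():
    inf = random_influence(n_vox=500, n_spots=15, seed=24)
    rois = make_rois(inf.shape, ("t", "target", slice(0, 350)))
    objs = ObjectiveSet(
        [ObjectiveTerm("t", "dose", "uniform", 1.0, 1.0),
         ObjectiveTerm("t", "letd", "min", 8.0, 1.0)]
    )
    w0 = init_weights(inf, rois, "t", 1.0)
    factor, w, _ = tune_let_penalties(inf, objs, rois, "t", 1.0, w0)
    rows = inf.rows_for_mask(rois["t"].mask)
    dose_only, _ = solve_weights(inf, objs.with_let_penalties_zeroed(), rois, w0)
    d95_ref = np.percentile((inf.D @ dose_only)[rows], 5)
    d95 = np.percentile((inf.D @ w)[rows], 5)
    assert d95 >= d95_ref * 0.99
    assert factor >= 0.0


def test_dvh_term_penalizes_only_excess_voxels():
    rng = np.random.default_rng(25)
    D = sparse.csc_matrix(np.diag(np.linspace(0.5, 2.0, 10)))
    L = sparse.csc_matrix(np.eye(10))
    inf = InfluencePair(D, L, np.arange(10), (10, 1, 1))
    rois = make_rois(inf.shape, ("t", "target", slice(0, 4)),
                     ("o", "oar", slice(0, 10)))
    objs = ObjectiveSet(
        [ObjectiveTerm("t", "dose", "uniform", 1.0, 0.0),
         ObjectiveTerm("o", "dose", "max_dvh", 1.0, 1.0, volume_fraction=0.3)]
    )
    w = np.ones(10)
    dose = (inf.D @ w)
    over = dose > 1.0
    allowed = int(np.floor(0.3 * 10))
    excess = int(over.sum()) - allowed
    # the `excess` overshooting voxels closest to the level are penalized
    overs = np.sort(dose[over] - 1.0)
    expected = float(np.sum(overs[:excess] ** 2)) / 10.0
    assert objective_value(w, objs, inf, rois) == pytest.approx(expected)
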