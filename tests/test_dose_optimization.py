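"""Dose redistribution: objectives, gradients, KKT solver vs oracles."""

import numpy as np
import pytest

from dosepaint.dose_optimization import (DoseConstraints, DosePlan,
                                         objective_std, objective_surv,
                                         optimize, project_mean_box,
                                         survivors_per_voxel, uniform_plan)
from dosepaint.radiobiology import FULLY_OXIC_PO2, LQParams, OERParams

CENTERS2 = np.array([0.0, FULLY_OXIC_PO2])


def two_voxel_problem():
    """One anoxic and one fully oxic voxel with equal cell counts."""
    viable = np.array([1.0e6, 1.0e6])
    weights = np.array([[1.0, 0.0], [0.0, 1.0]])
    return viable, weights


def random_problem(rng, n=6):
    viable = rng.uniform(1e4, 1e6, n)
    weights = rng.dirichlet(np.ones(4), size=n)
    centers = np.sort(rng.uniform(0, 40, 4))
    return viable, weights, centers


class TestObjectives:
    def test_surv_gradient_matches_finite_differences(self, lq, oer_params):
        rng = np.random.default_rng(0)
        viable, weights, centers = random_problem(rng)
        d = rng.uniform(1.5, 2.5, viable.size)
        _, grad = objective_surv(d, viable, weights, centers, lq, oer_params)
        eps = 1e-6
        for i in range(d.size):
            dp, dm = d.copy(), d.copy()
            dp[i] += eps
            dm[i] -= eps
            fd = (objective_surv(dp, viable, weights, centers, lq, oer_params)[0]
                  - objective_surv(dm, viable, weights, centers, lq, oer_params)[0]
                  ) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-6)

    def test_std_gradient_matches_finite_differences(self, lq, oer_params):
        rng = np.random.default_rng(1)
        viable, weights, centers = random_problem(rng)
        d = rng.uniform(1.5, 2.5, viable.size)
        _, grad = objective_std(d, viable, weights, centers, lq, oer_params)
        eps = 1e-6
        for i in range(d.size):
            dp, dm = d.copy(), d.copy()
            dp[i] += eps
            dm[i] -= eps
            fd = (objective_std(dp, viable, weights, centers, lq, oer_params)[0]
                  - objective_std(dm, viable, weights, centers, lq, oer_params)[0]
                  ) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_surv_zero_for_empty_tumor(self, lq, oer_params):
        value, _ = objective_surv(np.array([2.0, 2.0]), np.zeros(2),
                                  np.ones((2, 1)) , np.array([5.0]), lq, oer_params)
        assert value == 0.0

    def test_std_zero_for_identical_voxels_uniform_dose(self, lq, oer_params):
        viable = np.full(4, 1e5)
        weights = np.tile([0.5, 0.5], (4, 1))
        value, _ = objective_std(np.full(4, 2.0), viable, weights, CENTERS2,
                                 lq, oer_params)
        assert value == pytest.approx(0.0, abs=1e-9)

    def test_std_permutation_invariant(self, lq, oer_params):
        rng = np.random.default_rng(2)
        viable, weights, centers = random_problem(rng)
        d = rng.uniform(1.5, 2.5, viable.size)
        v1, _ = objective_std(d, viable, weights, centers, lq, oer_params)
        perm = rng.permutation(viable.size)
        v2, _ = objective_std(d[perm], viable[perm], weights[perm], centers,
                              lq, oer_params)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_std_hand_computed_three_voxels(self, lq, oer_params):
        """Spreadsheet-style check on a 3-voxel fixture."""
        viable = np.array([100.0, 200.0, 300.0])
        weights = np.array([[1.0], [1.0], [1.0]])
        centers = np.array([FULLY_OXIC_PO2])
        d = np.array([2.0, 2.0, 2.0])
        s = viable * np.exp(-0.35 * 2 - 0.035 * 4)
        expected = float(np.std(s))
        got, _ = objective_std(d, viable, weights, centers, lq, oer_params)
        assert got == pytest.approx(expected, rel=1e-3)


class TestProjection:
    def test_projection_feasible_and_idempotent(self, constraints):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 4, 50)
        d = project_mean_box(x, constraints)
        assert d.mean() == pytest.approx(2.0, abs=1e-6)
        assert d.min() >= 1.5 - 1e-9 and d.max() <= 2.5 + 1e-9
        again = project_mean_box(d, constraints)
        assert np.allclose(again, d, atol=1e-6)


class TestUniformPlan:
    def test_mean_and_feasibility(self, constraints):
        plan = uniform_plan(10, constraints)
        assert plan.doses.mean() == 2.0
        assert plan.objective == "uniform"

    def test_plan_validation(self, constraints):
        with pytest.raises(ValueError):
            DosePlan(np.full(4, 3.0), constraints, "uniform")
        with pytest.raises(ValueError):
            DosePlan(np.array([1.5, 1.5, 1.6, 1.6]), constraints, "uniform")


class TestOptimize:
    def test_homogeneous_tumor_yields_uniform(self, lq, oer_params, constraints):
        viable = np.full(8, 1e5)
        weights = np.tile([0.0, 1.0], (8, 1))
        plan = optimize(viable, weights, CENTERS2, lq, oer_params,
                        objective="surv", constraints=constraints)
        assert np.allclose(plan.doses, 2.0, atol=1e-3)

    def test_two_voxel_vs_brute_force(self, lq, oer_params, constraints):
        """Exhaustive search over feasible (d1, 4-d1) at 1 mGy resolution."""
        viable, weights = two_voxel_problem()
        plan = optimize(viable, weights, CENTERS2, lq, oer_params,
                        objective="surv", constraints=constraints)
        d1 = np.arange(1.5, 2.5 + 1e-9, 1e-3)
        grid_vals = [objective_surv(np.array([a, 4.0 - a]), viable, weights,
                                    CENTERS2, lq, oer_params)[0] for a in d1]
        best = d1[int(np.argmin(grid_vals))]
        assert plan.doses[0] == pytest.approx(best, abs=1e-3)
        assert plan.doses.mean() == pytest.approx(2.0, abs=1e-6)

    def test_boost_follows_marginal_kill(self, lq, oer_params, constraints):
        """With equal cell counts the oxic voxel is boosted (its marginal
        kill per Gy is larger); once the hypoxic voxel's survivors dominate
        -- the situation after a few fractions -- the boost flips to it."""
        viable, weights = two_voxel_problem()
        plan = optimize(viable, weights, CENTERS2, lq, oer_params,
                        objective="surv", constraints=constraints)
        assert plan.doses[1] > plan.doses[0]  # equal counts: oxic boosted
        viable = np.array([1.0e6, 1.0e3])  # hypoxic survivors dominate
        plan = optimize(viable, weights, CENTERS2, lq, oer_params,
                        objective="surv", constraints=constraints)
        assert plan.doses[0] > plan.doses[1]  # anoxic voxel boosted

    def test_kkt_matches_slsqp_on_random_instances(self, lq, oer_params,
                                                   constraints):
        """Two independent algorithms agree on the convex objective."""
        rng = np.random.default_rng(7)
        for _ in range(3):
            viable, weights, centers = random_problem(rng, n=8)
            kkt = optimize(viable, weights, centers, lq, oer_params,
                           objective="surv", constraints=constraints, method="kkt")
            ref = optimize(viable, weights, centers, lq, oer_params,
                           objective="surv", constraints=constraints, method="slsqp")
            f_kkt = objective_surv(kkt.doses, viable, weights, centers, lq,
                                   oer_params)[0]
            f_ref = objective_surv(ref.doses, viable, weights, centers, lq,
                                   oer_params)[0]
            # agreement in objective value; KKT is never worse than SLSQP
            assert f_kkt <= f_ref * (1 + 1e-9)
            assert f_kkt == pytest.approx(f_ref, rel=1e-3)

    def test_feasibility_always(self, lq, oer_params, constraints):
        rng = np.random.default_rng(8)
        for objective in ("surv", "std"):
            viable, weights, centers = random_problem(rng, n=10)
            plan = optimize(viable, weights, centers, lq, oer_params,
                            objective=objective, constraints=constraints)
            assert plan.doses.mean() == pytest.approx(2.0, abs=1e-6)
            assert plan.doses.min() >= 1.5 - 1e-6
            assert plan.doses.max() <= 2.5 + 1e-6

    def test_never_worse_than_uniform(self, lq, oer_params, constraints):
        rng = np.random.default_rng(9)
        for objective in ("surv", "std"):
            viable, weights, centers = random_problem(rng, n=12)
            plan = optimize(viable, weights, centers, lq, oer_params,
                            objective=objective, constraints=constraints)
            fun = objective_surv if objective == "surv" else objective_std
            f_opt = fun(plan.doses, viable, weights, centers, lq, oer_params)[0]
            f_uni = fun(np.full(12, 2.0), viable, weights, centers, lq, oer_params)[0]
            assert f_opt <= f_uni + 1e-9

    def test_reoptimization_idempotent(self, lq, oer_params, constraints):
        viable, weights = two_voxel_problem()
        p1 = optimize(viable, weights, CENTERS2, lq, oer_params,
                      objective="surv", constraints=constraints)
        f1 = p1.solver_report["objective_value"]
        p2 = optimize(viable, weights, CENTERS2, lq, oer_params,
                      objective="surv", constraints=constraints)
        assert abs(p2.solver_report["objective_value"] - f1) < 1e-9

    def test_std_beats_uniform_on_heterogeneous_toy(self, lq, oer_params,
                                                    constraints):
        viable = np.array([1e6, 1e5, 5e5, 2e5])
        weights = np.tile([0.0, 1.0], (4, 1))
        plan = optimize(viable, weights, CENTERS2, lq, oer_params,
                        objective="std", constraints=constraints)
        f_opt = objective_std(plan.doses, viable, weights, CENTERS2, lq,
                              oer_params)[0]
        f_uni = objective_std(np.full(4, 2.0), viable, weights, CENTERS2, lq,
                              oer_params)[0]
        assert f_opt < f_uni
        # the densest voxel is boosted toward survivor equalization
        assert plan.doses[0] == plan.doses.max()

    def test_empty_grid_rejected(self, lq, oer_params, constraints):
        with pytest.raises(ValueError):
            optimize(np.array([]), np.zeros((0, 2)), CENTERS2, lq, oer_params,
                     objective="surv", constraints=constraints)

    def test_dead_voxels_released_to_minimum_dose(self, lq, oer_params,
                                                  constraints):
        """Cleared voxels surrender dose budget to the surviving ones."""
        viable = np.array([1e6, 0.0, 0.0, 0.0])
        weights = np.tile([1.0, 0.0], (4, 1))
        plan = optimize(viable, weights, CENTERS2, lq, oer_params,
                        objective="surv", constraints=constraints)
        assert plan.doses[0] == pytest.approx(2.5, abs=1e-6)
        # the cleared voxels split the remaining budget equally
        assert np.allclose(plan.doses[1:], (8.0 - 2.5) / 3, atol=1e-6)
        assert plan.doses.mean() == pytest.approx(2.0, abs=1e-6)
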