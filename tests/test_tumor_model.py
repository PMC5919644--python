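"""Tumor response dynamics: per-process laws, conservation, stochastic kill."""

import numpy as np
import pytest

from dosepaint.radiobiology import FULLY_OXIC_PO2
from dosepaint.tumor_model import (BioParams, HOURS_PER_DAY, TumorGrid,
                                   angiogenesis, exchange_cells, irradiate,
                                   proliferate, resorb_dead, step_day)
from conftest import make_toy_grid


class TestProliferate:
    def test_doubling_closed_form(self, bio, lookup):
        grid = make_toy_grid([1000.0])
        proliferate(grid, 120.0, bio, tp_hours=120.0)
        assert grid.viable[0, 0, 0, 0] == pytest.approx(2000.0)

    def test_zero_dt_unchanged(self, bio):
        grid = make_toy_grid([1000.0])
        proliferate(grid, 0.0, bio)
        assert grid.viable[0, 0, 0, 0] == 1000.0

    def test_accelerated_repopulation_switch(self, bio):
        """Doubling time drops from 1200 h to 120 h after two weeks."""
        assert bio.tp_effective(13.0) == 1200.0
        assert bio.tp_effective(15.0) == 120.0
        g13 = make_toy_grid([1000.0]); g13.time_days = 13.0
        g15 = make_toy_grid([1000.0]); g15.time_days = 15.0
        proliferate(g13, 24.0, bio)
        proliferate(g15, 24.0, bio)
        assert g13.viable[0, 0, 0, 0] == pytest.approx(1000 * 2 ** (24 / 1200))
        assert g15.viable[0, 0, 0, 0] == pytest.approx(1000 * 2 ** (24 / 120))

    def test_capacity_suppression_and_vessel_crush(self, bio):
        grid = make_toy_grid([1.0])
        cap = grid.capacity
        grid.viable[:] = 0.97 * cap
        grid.capillary[:] = 0.03 * cap
        before_cap = grid.capillary[0, 0, 0, 0]
        proliferate(grid, 24.0, bio, tp_hours=120.0)
        assert grid.viable[0, 0, 0, 0] == 0.97 * cap  # no growth at capacity
        assert grid.capillary[0, 0, 0, 0] < before_cap  # crushed instead
        # never below the vascular floor
        for _ in range(300):
            proliferate(grid, 24.0, bio, tp_hours=120.0)
        assert grid.capillary[0, 0, 0, 0] >= bio.vf_floor * cap - 1e-9

    def test_normal_atrophy_under_tumor_pressure(self, bio):
        grid = make_toy_grid([0.0])
        grid.normal[:] = 1000.0
        proliferate(grid, 24.0, bio)  # no tumor -> no atrophy
        assert grid.normal[0, 0, 0, 0] == pytest.approx(1000.0)
        grid.viable[:] = grid.capacity * 0.5
        proliferate(grid, bio.normal_atrophy_time / 0.5, bio, tp_hours=1e9)
        assert grid.normal[0, 0, 0, 0] == pytest.approx(500.0)


class TestResorb:
    def test_half_life(self, bio):
        grid = make_toy_grid([0.0])
        grid.dead[:] = 1000.0
        resorb_dead(grid, 168.0, bio)
        assert grid.dead[0, 0, 0, 0] == pytest.approx(500.0)

    def test_semigroup(self, bio):
        g1 = make_toy_grid([0.0]); g1.dead[:] = 1000.0
        g2 = make_toy_grid([0.0]); g2.dead[:] = 1000.0
        resorb_dead(g1, 168.0, bio)
        resorb_dead(g2, 84.0, bio)
        resorb_dead(g2, 84.0, bio)
        assert g1.dead[0, 0, 0, 0] == pytest.approx(g2.dead[0, 0, 0, 0])

    def test_zero_dt(self, bio):
        grid = make_toy_grid([0.0]); grid.dead[:] = 77.0
        resorb_dead(grid, 0.0, bio)
        assert grid.dead[0, 0, 0, 0] == 77.0


class TestAngiogenesis:
    def test_hypoxic_voxel_doubles_at_ta(self, bio, lookup):
        grid = make_toy_grid([1.0e6], vf=0.005)  # hypoxic: tiny vf, full consumption
        before = grid.capillary.copy()
        angiogenesis(grid, bio.ta, bio, lookup)
        assert grid.capillary[0, 0, 0, 0] == pytest.approx(2 * before[0, 0, 0, 0])

    def test_oxygenated_voxel_unchanged(self, bio, lookup):
        grid = make_toy_grid([1.0e6], vf=0.06)
        before = grid.capillary.copy()
        angiogenesis(grid, 612.0, bio, lookup)
        assert np.allclose(grid.capillary, before)

    def test_empty_voxel_unchanged(self, bio, lookup):
        grid = make_toy_grid([0.0], vf=0.005)
        grid.capillary[:] = 50.0
        angiogenesis(grid, 612.0, bio, lookup)
        assert np.allclose(grid.capillary, 50.0)


class TestIrradiate:
    def test_zero_dose_noop(self, bio, lq, oer_params, lookup, toy_grid):
        before = toy_grid.viable.copy()
        irradiate(toy_grid, np.zeros(3), lq, oer_params, lookup, bio=bio)
        assert np.allclose(toy_grid.viable, before)

    def test_mass_balance(self, bio, lq, oer_params, lookup, toy_grid):
        total_before = toy_grid.viable.sum() + toy_grid.dead.sum()
        irradiate(toy_grid, np.full(3, 2.0), lq, oer_params, lookup, bio=bio)
        total_after = toy_grid.viable.sum() + toy_grid.dead.sum()
        assert total_after == pytest.approx(total_before, rel=1e-12)

    def test_insane_dose_rejected(self, bio, lq, oer_params, lookup, toy_grid):
        with pytest.raises(ValueError):
            irradiate(toy_grid, np.full(3, 50.0), lq, oer_params, lookup, bio=bio)

    def test_plan_shape_checked(self, bio, lq, oer_params, lookup, toy_grid):
        with pytest.raises(ValueError):
            irradiate(toy_grid, np.full(2, 2.0), lq, oer_params, lookup, bio=bio)

    def test_stochastic_mean_matches_expectation(self, bio, lq, oer_params, lookup):
        """Binomial kill is unbiased: the mean over many draws reproduces the
        expected-value kill within 3 standard errors."""
        n_rep = 200
        grid = make_toy_grid([5000.0], vf=0.06, batch=n_rep)
        rng = np.random.default_rng(11)
        irradiate(grid, np.array([2.0]), lq, oer_params, lookup, rng=rng, bio=bio)
        realized = grid.viable[:, 0, 0, 0]
        det = make_toy_grid([5000.0], vf=0.06)
        irradiate(det, np.array([2.0]), lq, oer_params, lookup, bio=bio)
        expected = det.viable[0, 0, 0, 0]
        se = realized.std(ddof=1) / np.sqrt(n_rep)
        assert abs(realized.mean() - expected) < 3 * se + 1e-9
        assert np.allclose(realized, np.round(realized))  # integerized

    def test_large_voxels_use_expected_value(self, bio, lq, oer_params, lookup):
        g1 = make_toy_grid([5.0e6], vf=0.06)
        g2 = make_toy_grid([5.0e6], vf=0.06)
        irradiate(g1, np.array([2.0]), lq, oer_params, lookup, bio=bio)
        irradiate(g2, np.array([2.0]), lq, oer_params, lookup,
                  rng=np.random.default_rng(0), bio=bio)
        assert g1.viable[0, 0, 0, 0] == g2.viable[0, 0, 0, 0]


class TestExchange:
    def test_at_capacity_fixed_point(self, bio):
        grid = make_toy_grid([0.0] * 3)
        grid.viable[:] = grid.capacity
        before = grid.viable.copy()
        exchange_cells(grid, bio)
        assert np.allclose(grid.viable, before)

    def test_overfull_voxel_splits_excess_to_neighbors(self, bio):
        grid = TumorGrid((3, 3, 3), 1.124, 1e6)
        grid.tumor_mask[:] = True
        cap = grid.capacity
        grid.viable[0, 1, 1, 1] = 2.0 * cap
        exchange_cells(grid, bio)
        center = grid.viable[0, 1, 1, 1]
        neighbors = [grid.viable[0, 0, 1, 1], grid.viable[0, 2, 1, 1],
                     grid.viable[0, 1, 0, 1], grid.viable[0, 1, 2, 1],
                     grid.viable[0, 1, 1, 0], grid.viable[0, 1, 1, 2]]
        assert center <= cap * 1.0001
        assert np.allclose(neighbors, neighbors[0])  # equal split
        assert neighbors[0] > 0

    def test_conservation_of_every_compartment(self, bio):
        rng = np.random.default_rng(5)
        grid = TumorGrid((6, 6, 6), 1.124, 1e6, batch=2)
        grid.tumor_mask[:] = True
        for comp in grid.compartments:
            comp[:] = rng.uniform(0, 1.5 * grid.capacity, comp.shape)
        totals = [c.sum() for c in grid.compartments]
        exchange_cells(grid, bio)
        for comp, before in zip(grid.compartments, totals):
            assert comp.sum() == pytest.approx(before, rel=1e-9)

    def test_diffusion_moves_down_gradient(self, bio):
        grid = TumorGrid((2, 1, 1), 1.124, 1e6)
        grid.tumor_mask[:] = True
        grid.viable[0, 0, 0, 0] = 0.8 * grid.capacity
        exchange_cells(grid, bio)
        assert grid.viable[0, 1, 0, 0] > 0
        assert grid.viable[0, 0, 0, 0] < 0.8 * grid.capacity


class TestStepDay:
    def test_invariant_without_processes(self, lq, oer_params, lookup):
        """With no dose, no dead cells and frozen proliferation the state is
        a fixed point of the daily loop."""
        bio = BioParams(tp_initial=1e12, tp_accelerated=1e12, growth_tp=1e12)
        grid = make_toy_grid([0.5e6, 0.5e6], vf=0.06)
        before = [c.copy() for c in grid.compartments]
        step_day(grid, None, bio, lq, oer_params, lookup)
        for c, b in zip(grid.compartments, before):
            assert np.allclose(c, b, rtol=1e-9)
        assert grid.time_days == 1.0

    def test_weekend_day_grows_slightly(self, bio, lq, oer_params, lookup):
        grid = make_toy_grid([1.0e5], vf=0.06)
        step_day(grid, None, bio, lq, oer_params, lookup)
        assert 1.0e5 < grid.viable.sum() < 1.03e5  # tp = 1200 h: ~1.4%/day

    def test_treatment_day_shrinks(self, bio, lq, oer_params, lookup, toy_grid):
        before = toy_grid.total_viable()[0]
        step_day(toy_grid, np.full(3, 2.0), bio, lq, oer_params, lookup)
        assert toy_grid.total_viable()[0] < before

    def test_deterministic_reproducibility(self, bio, lq, oer_params, lookup):
        outs = []
        for _ in range(2):
            grid = make_toy_grid([1e6, 4e5], vf=0.03)
            rng = np.random.default_rng(123)
            for _ in range(3):
                step_day(grid, np.full(2, 2.0), bio, lq, oer_params, lookup, rng=rng)
            outs.append(grid.viable.copy())
        assert np.array_equal(outs[0], outs[1])


def test_doubling_time_recovery(bio, lq, oer_params, lookup):
    """A silent (no-dose) run recovers the configured doubling time within 2%
    when fitting an exponential to the viable-cell trajectory."""
    grid = make_toy_grid([1.0e4], vf=0.06)
    days, counts = [], []
    for day in range(10):
        days.append(day)
        counts.append(grid.total_viable()[0])
        step_day(grid, None, bio, lq, oer_params, lookup)
    rate = np.polyfit(days, np.log2(counts), 1)[0]  # doublings/day
    tp_fit = 24.0 / rate
    assert tp_fit == pytest.approx(bio.tp_initial, rel=0.02)
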