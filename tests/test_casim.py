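import warnings

import numpy as np
import pytest

from greenscape.casim import (
    ConversionCostMatrix,
    DemandSeries,
    ECOLOGICAL_PROTECTION,
    NeighborhoodWeights,
    ScenarioConfig,
    apply_scenario,
    kappa_oa,
    project_demand,
    simulate,
)
from greenscape.change import TransitionMatrix
from greenscape.grid import ClassEntry, ClassScheme, LandCoverGrid, MaskGrid
from greenscape.suitability import SuitabilityCube


def two_class_tm(P, t0=(1000.0, 1000.0), years=10.0):
    area = np.asarray(P) * np.asarray(t0)[:, None]
    return TransitionMatrix(area=area, years=years)


class TestProjectDemand:
    def test_identity_keeps_current(self):
        tm = two_class_tm(np.eye(2))
        d = project_demand(tm, np.array([1000.0, 1000.0]), steps=3)
        np.testing.assert_array_equal(d.target_cells, [1000, 1000])

    def test_one_step_matrix_multiply(self):
        tm = two_class_tm([[0.9, 0.1], [0.2, 0.8]])
        d = project_demand(tm, np.array([1000.0, 1000.0]), steps=1)
        np.testing.assert_array_equal(d.target_cells, [1100, 900])

    def test_two_steps_squared_matrix(self):
        tm = two_class_tm([[0.9, 0.1], [0.2, 0.8]])
        d = project_demand(tm, np.array([1000.0, 1000.0]), steps=2)
        np.testing.assert_array_equal(d.target_cells, [1170, 830])

    def test_zero_area_row_defaults_to_identity(self):
        area = np.array([[90.0, 10.0], [0.0, 0.0]])
        tm = TransitionMatrix(area=area, years=10)
        d = project_demand(tm, np.array([100.0, 0.0]), steps=1)
        assert d.target_cells.sum() == 100

    def test_rounding_preserves_total(self):
        tm = two_class_tm([[0.85, 0.15], [0.33, 0.67]], t0=(777.0, 334.0))
        d = project_demand(tm, np.array([777.0, 334.0]), steps=1)
        assert d.target_cells.sum() == 1111


class TestApplyScenario:
    def test_empty_multipliers_noop(self):
        tm = two_class_tm([[0.9, 0.1], [0.2, 0.8]])
        out = apply_scenario(tm, ScenarioConfig(name="status_quo"))
        np.testing.assert_allclose(out.area, tm.area)

    def test_halving_routes_mass_to_diagonal(self):
        tm = two_class_tm([[0.90, 0.10], [0.0, 1.0]])
        out = apply_scenario(
            tm, ScenarioConfig(name="eco", multipliers={(0, 1): 0.5})
        )
        np.testing.assert_allclose(out.row_probabilities()[0], [0.95, 0.05])

    def test_increase_draws_mass_from_diagonal(self):
        tm = two_class_tm([[0.90, 0.10], [0.0, 1.0]])
        out = apply_scenario(
            tm, ScenarioConfig(name="econ", multipliers={(0, 1): 1.5})
        )
        np.testing.assert_allclose(out.row_probabilities()[0], [0.85, 0.15])

    def test_rows_stay_stochastic(self):
        rng = np.random.default_rng(0)
        P = rng.dirichlet(np.ones(7), size=7)
        tm = TransitionMatrix(area=P * 100.0, years=10)
        out = apply_scenario(tm, ECOLOGICAL_PROTECTION)
        np.testing.assert_allclose(
            out.row_probabilities().sum(axis=1), 1.0, atol=1e-9
        )

    def test_negative_diagonal_rejected(self):
        tm = two_class_tm([[0.10, 0.90], [0.0, 1.0]])
        with pytest.raises(ValueError, match="row 0"):
            apply_scenario(
                tm, ScenarioConfig(name="bad", multipliers={(0, 1): 1.5})
            )


def _ab_scheme():
    return ClassScheme((ClassEntry(1, "a", True), ClassEntry(2, "b", False)))


def _uniform_cube(grid, k):
    n = grid.n_valid
    return SuitabilityCube(prob=np.full((n, k), 1.0 / k), valid=grid.valid_mask)


class TestSimulate:
    def test_demand_equals_current_is_identity(self):
        sch = _ab_scheme()
        values = np.ones((20, 20), dtype=int)
        values[:5] = 2
        grid = LandCoverGrid(values, scheme=sch)
        counts = np.array([(values == 1).sum(), (values == 2).sum()])
        out, rep = simulate(grid, _uniform_cube(grid, 2),
                            DemandSeries(counts), seed=0)
        np.testing.assert_array_equal(out.values, grid.values)
        assert rep.iterations == 0 and rep.converged

    def test_all_masked_with_current_demand_is_identity(self):
        sch = _ab_scheme()
        values = np.ones((10, 10), dtype=int)
        values[0] = 2
        grid = LandCoverGrid(values, scheme=sch)
        counts = np.array([90, 10])
        mask = MaskGrid(np.ones((10, 10), dtype=bool))
        out, _ = simulate(grid, _uniform_cube(grid, 2),
                          DemandSeries(counts), mask=mask, seed=0)
        np.testing.assert_array_equal(out.values, grid.values)

    def test_growth_clusters_near_seeds(self):
        """New B cells hug the B seed patch more than random cells would."""
        sch = _ab_scheme()
        rng = np.random.default_rng(0)
        values = np.ones((50, 50), dtype=int)
        values[20:22, 20:25] = 2  # 10 seed B cells
        grid = LandCoverGrid(values, scheme=sch)
        cost = ConversionCostMatrix(np.array([[1, 1], [0, 1]]))
        demand = DemandSeries(np.array([2500 - 210, 210]))
        out, rep = simulate(grid, _uniform_cube(grid, 2), demand,
                            cost=cost, seed=1)
        b_cells = (out.values == 2).sum()
        assert abs(b_cells - 210) <= max(1, int(0.001 * 2500))
        seeds = np.argwhere(values == 2)
        new_b = np.argwhere((out.values == 2) & (values == 1))

        def mean_dist(points):
            d = np.linalg.norm(
                points[:, None, :] - seeds[None, :, :], axis=-1
            ).min(axis=1)
            return d.mean()

        rand_cells = np.argwhere(values == 1)
        rand_pick = rand_cells[rng.choice(len(rand_cells), 200, replace=False)]
        assert mean_dist(new_b) < mean_dist(rand_pick)

    def test_masked_cells_bit_identical(self):
        sch = _ab_scheme()
        rng = np.random.default_rng(2)
        values = rng.choice([1, 2], size=(40, 40), p=[0.7, 0.3])
        grid = LandCoverGrid(values, scheme=sch)
        mask = MaskGrid(rng.random((40, 40)) < 0.2)
        counts = np.array([(values == 1).sum() - 50, (values == 2).sum() + 50])
        out, _ = simulate(grid, _uniform_cube(grid, 2),
                          DemandSeries(counts), mask=mask, seed=3)
        np.testing.assert_array_equal(
            out.values[mask.values], grid.values[mask.values]
        )

    def test_forbidden_conversions_never_occur(self):
        sch = _ab_scheme()
        rng = np.random.default_rng(4)
        values = rng.choice([1, 2], size=(40, 40), p=[0.6, 0.4])
        grid = LandCoverGrid(values, scheme=sch)
        cost = ConversionCostMatrix(np.array([[1, 1], [0, 1]]))  # B frozen
        counts = np.array([(values == 1).sum() - 80, (values == 2).sum() + 80])
        out, _ = simulate(grid, _uniform_cube(grid, 2),
                          DemandSeries(counts), cost=cost, seed=5)
        changed = out.values != values
        assert not ((values == 2) & changed).any()

    def test_infeasible_demand_raises_before_iterating(self):
        sch = _ab_scheme()
        values = np.ones((10, 10), dtype=int)
        values[0, 0] = 2
        grid = LandCoverGrid(values, scheme=sch)
        cost = ConversionCostMatrix(np.array([[1, 0], [1, 1]]))  # no A->B
        with pytest.raises(ValueError, match="infeasible"):
            simulate(grid, _uniform_cube(grid, 2),
                     DemandSeries(np.array([50, 50])), cost=cost, seed=0)

    def test_reproducible_given_seed(self):
        sch = _ab_scheme()
        rng = np.random.default_rng(6)
        values = rng.choice([1, 2], size=(50, 50), p=[0.6, 0.4])
        grid = LandCoverGrid(values, scheme=sch)
        counts = np.array([(values == 1).sum() - 100, (values == 2).sum() + 100])
        a, _ = simulate(grid, _uniform_cube(grid, 2), DemandSeries(counts), seed=7)
        b, _ = simulate(grid, _uniform_cube(grid, 2), DemandSeries(counts), seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_cell_total_conserved(self):
        sch = _ab_scheme()
        rng = np.random.default_rng(8)
        values = rng.choice([1, 2], size=(30, 30), p=[0.5, 0.5])
        grid = LandCoverGrid(values, scheme=sch)
        counts = np.array([(values == 1).sum() + 60, (values == 2).sum() - 60])
        out, _ = simulate(grid, _uniform_cube(grid, 2), DemandSeries(counts), seed=9)
        assert (out.values > 0).sum() == 900


class TestKappaOA:
    def test_identical_maps(self, uniform_grid):
        kappa, oa, _ = kappa_oa(uniform_grid, uniform_grid)
        assert kappa == 1.0 and oa == 1.0

    def test_known_confusion(self):
        # confusion [[45, 5], [5, 45]]: OA 0.9, p_e 0.5, kappa 0.8
        sch = _ab_scheme()
        a = np.ones(100, dtype=int)
        a[50:] = 2
        b = a.copy()
        b[:5] = 2
        b[50:55] = 1
        kappa, oa, conf = kappa_oa(
            LandCoverGrid(a.reshape(10, 10), scheme=sch),
            LandCoverGrid(b.reshape(10, 10), scheme=sch),
        )
        assert oa == pytest.approx(0.9)
        assert kappa == pytest.approx(0.8)
        np.testing.assert_array_equal(conf, [[45, 5], [5, 45]])

    def test_single_class_maps(self):
        sch = _ab_scheme()
        a = LandCoverGrid(np.ones((5, 5), dtype=int), scheme=sch)
        b = LandCoverGrid(np.full((5, 5), 2), scheme=sch)
        kappa_same, _, _ = kappa_oa(a, a)
        kappa_diff, _, _ = kappa_oa(a, b)
        assert kappa_same == 1.0
        assert kappa_diff == 0.0
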