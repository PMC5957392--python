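"""Invasion simulator: founder placement, annual dynamics, invariants."""

import numpy as np
import pytest

from invadescape import habitat
from invadescape.errors import ConfigurationError, DimensionError
from invadescape.landscapes import LandscapeRaster
from invadescape.simulate import (DispersalKernel, HabitatParams,
                                  InvasionState, Trajectory, TraitSet,
                                  build_trait_grid, initialize_invasion,
                                  run_simulation, step_year,
                                  summarize_trajectory)


def _grass(n, m=None):
    return LandscapeRaster(np.full((n, m or n), habitat.GRASSLAND))


class TestInitialization:
    def test_founder_block_totals(self):
        state = initialize_invasion(_grass(216))
        assert state.adults.sum() == 450
        assert (state.adults > 0).sum() == 9
        assert state.juveniles.sum() == 0
        assert state.year == 0

    def test_whole_raster_is_center_on_3x3(self):
        state = initialize_invasion(_grass(3))
        assert (state.adults == 50).all()

    def test_even_sided_raster_occupies_exactly_nine_cells(self):
        state = initialize_invasion(_grass(10))
        assert (state.adults > 0).sum() == 9
        # anchored at (3, 3) per the documented center convention
        assert (state.adults[3:6, 3:6] == 50).all()

    def test_too_small_raster_rejected(self):
        with pytest.raises(DimensionError):
            initialize_invasion(_grass(2))


class TestStepYear:
    def test_null_dynamics_change_only_the_year(self, params):
        raster = _grass(12)
        params = HabitatParams(fecundity=0.0)
        state = initialize_invasion(raster)
        traits = TraitSet(growth_mult=0.0, establishment_freq=0.01)
        out = step_year(state, raster, params, traits, DispersalKernel(),
                        np.random.default_rng(0))
        assert (out.adults == state.adults).all()
        assert (out.juveniles == 0).all()
        assert out.year == 1

    def test_zero_establishment_freezes_extent(self, params):
        raster = _grass(20)
        traits = TraitSet(1.0, 1.0, 0.0, 0.5)
        traj, summary = run_simulation(raster, params, traits,
                                       years=35, seed=3)
        assert (traj.occupied_cells == traj.occupied_cells[0]).all()
        assert summary.final_extent == 9 / raster.n_cells

    def test_shape_mismatch_rejected(self, mixed_raster, params):
        state = initialize_invasion(_grass(8))
        with pytest.raises(Exception):
            step_year(state, mixed_raster, params, TraitSet(),
                      DispersalKernel(), np.random.default_rng(0))

    def test_corridor_usage_extends_spread_along_roads(self, params):
        """A grassland pocket reachable only via a long road is colonized
        far more often when seeds ride corridors (paired experiment)."""
        grid = np.full((9, 80), habitat.UNSUITABLE, dtype=np.int16)
        grid[3:6, 38:41] = habitat.GRASSLAND      # founder island (center)
        grid[4, 41:72] = habitat.ROAD             # long corridor eastward
        grid[3:6, 70:73] = habitat.GRASSLAND      # pocket around the far end
        raster = LandscapeRaster(grid)
        extents = {0.0: [], 1.0: []}
        for usage in extents:
            traits = TraitSet(2.0, 1.0, 0.05, usage)
            for seed in range(200):
                _, s = run_simulation(raster, params, traits, years=12,
                                      seed=seed)
                extents[usage].append(s.final_extent)
        assert np.mean(extents[1.0]) > np.mean(extents[0.0])


class TestRunSimulation:
    def test_trajectory_has_years_plus_one_entries(self, mixed_raster, params):
        traj, _ = run_simulation(mixed_raster, params, TraitSet(), years=33,
                                 seed=0)
        assert len(traj) == 34

    def test_seed_determinism(self, mixed_raster, params):
        t1, s1 = run_simulation(mixed_raster, params, TraitSet(), years=20,
                                seed=5)
        t2, s2 = run_simulation(mixed_raster, params, TraitSet(), years=20,
                                seed=5)
        assert (t1.adults_total == t2.adults_total).all()
        assert (t1.occupied_cells == t2.occupied_cells).all()
        assert s1 == s2

    def test_founders_on_barren_landscape_go_extinct(self, params):
        raster = LandscapeRaster(np.full((15, 15), habitat.UNSUITABLE))
        traj, summary = run_simulation(raster, params, TraitSet(), years=35,
                                       seed=1)
        assert summary.final_extent == 0.0
        assert summary.final_population == 0.0
        # extinction exactly when the founder lifespan ends
        assert traj.adults_total[params.founder_lifespan_yr] == 0
        assert traj.adults_total[params.founder_lifespan_yr - 1] > 0

    def test_barrier_classes_never_hold_plants(self, mixed_raster, params):
        """Road, water and unsuitable cells outside the founder block stay
        empty through the whole run."""
        traits = TraitSet(2.0, 2.0, 0.05, 0.75)
        kernel = DispersalKernel()
        rng = np.random.default_rng(7)
        state = initialize_invasion(mixed_raster)
        founder = state.adults > 0
        barrier = np.isin(mixed_raster.grid,
                          list(habitat.BARRIER_CODES)) & ~founder
        K = params.K[mixed_raster.grid]
        for _ in range(25):
            state = step_year(state, mixed_raster, params, traits, kernel,
                              rng)
            assert state.adults[barrier].sum() == 0
            assert state.juveniles[barrier].sum() == 0
            # carrying capacity respected on all regulated cells
            assert (state.adults[K > 0] <= K[K > 0]).all()
            assert (state.adults >= 0).all() and (state.juveniles >= 0).all()

    def test_no_spontaneous_generation(self, mixed_raster, params):
        traits = TraitSet(2.0, 2.0, 0.0, 1.0)
        for seed in (0, 1, 2):
            traj, _ = run_simulation(mixed_raster, params, traits, years=15,
                                     seed=seed)
            assert (traj.occupied_cells <= 9).all()


class TestSummaries:
    def _traj(self, adults, occ, n_cells=100):
        n = len(adults)
        return Trajectory(np.arange(n), np.asarray(adults),
                          np.zeros(n, dtype=int), np.asarray(occ), n_cells)

    def test_stationary_trajectory(self):
        traj = self._traj([450] * 31, [9] * 31)
        s = summarize_trajectory(traj)
        assert s.growth_rate == 1.0
        assert s.expansion_rate == 0.0
        assert s.final_extent == 0.09
        assert s.final_population == 4.5

    def test_linear_occupancy_growth(self):
        occ = list(range(9, 40))
        traj = self._traj([450] * 31, occ)
        s = summarize_trajectory(traj)
        assert s.expansion_rate == pytest.approx(0.01)

    def test_extinction_reports_skipped_years(self):
        adults = [450] * 10 + [0] * 21
        occ = [9] * 10 + [0] * 21
        s = summarize_trajectory(self._traj(adults, occ))
        assert s.final_extent == 0.0
        assert s.final_population == 0.0
        assert s.skipped_years == 20
        # defined years: ratios over t=0..9 (one of them is the crash year)
        assert s.growth_rate == pytest.approx((1.0 * 9 + 0.0) / 10)

    def test_short_run_flags_reduced_transient_window(self, params):
        traj, s = run_simulation(_grass(9), params, TraitSet(), years=12,
                                 seed=0)
        assert s.transient_years_used == 12

    def test_too_short_trajectory_rejected(self):
        with pytest.raises(DimensionError):
            summarize_trajectory(self._traj([450], [9]))


def test_habitat_params_yaml_round_trip(tmp_path):
    params = HabitatParams(fecundity=150.0, founder_lifespan_yr=3)
    path = tmp_path / "demography.yaml"
    params.to_yaml(path)
    back = HabitatParams.from_yaml(path)
    np.testing.assert_allclose(back.r, params.r)
    assert (back.K == params.K).all()
    assert back.fecundity == 150.0
    assert back.founder_lifespan_yr == 3


class TestTraitGrid:
    def test_full_grid_has_500_unique_combinations(self):
        grid = build_trait_grid()
        assert len(grid) == 500
        assert len(set(grid)) == 500

    def test_level_values_match_design(self):
        grid = build_trait_grid()
        assert {t.dispersal_mult for t in grid} == {0.33, 0.5, 1.0, 1.5, 2.0}
        assert {t.establishment_freq for t in grid} == {0.005, 0.01, 0.025,
                                                        0.05}
        assert {t.corridor_usage for t in grid} == {0.0, 0.25, 0.5, 0.75, 1.0}

    def test_invalid_trait_levels_rejected(self):
        with pytest.raises(ConfigurationError):
            TraitSet(corridor_usage=1.5)
        with pytest.raises(ConfigurationError):
            TraitSet(establishment_freq=-0.1)
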