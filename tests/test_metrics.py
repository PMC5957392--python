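"""Landscape metric computations against closed forms and the brute-force
oracle."""

import math

import numpy as np
import pytest

from invadescape import habitat
from invadescape.errors import ConfigurationError
from invadescape.landscapes import LandscapeConfig, LandscapeRaster, \
    generate_landscape
from invadescape.metrics import (METRIC_NAMES, aggregation_metrics,
                                 composition_proportions,
                                 compute_metric_vector, diversity_metrics,
                                 label_patches, patch_distribution_stats)
from invadescape.metrics_oracle import oracle_metric_vector

GRASS, CROP = habitat.GRASSLAND, habitat.CROP


class TestLabeling:
    def test_uniform_raster_is_one_patch(self, uniform_grass):
        assert label_patches(uniform_grass).n_patches == 1

    def test_checkerboard_connectivity_4(self, checkerboard):
        pm = label_patches(checkerboard, connectivity=4)
        assert pm.n_patches == checkerboard.n_cells

    def test_checkerboard_connectivity_8(self, checkerboard):
        pm = label_patches(checkerboard, connectivity=8)
        assert pm.n_patches == 2

    def test_labels_partition_the_raster(self, mixed_raster):
        pm = label_patches(mixed_raster)
        assert pm.cell_count.sum() == mixed_raster.n_cells
        assert (np.sort(np.unique(pm.labels)) == np.arange(
            1, pm.n_patches + 1)).all()

    def test_invalid_connectivity_rejected(self, uniform_grass):
        with pytest.raises(ConfigurationError):
            label_patches(uniform_grass, connectivity=6)


class TestComposition:
    def test_uniform(self, uniform_grass):
        props = composition_proportions(uniform_grass)
        assert props[GRASS] == 1.0
        assert props.sum() == 1.0

    def test_half_and_half(self, half_and_half):
        props = composition_proportions(half_and_half)
        assert props[GRASS] == 0.5
        assert props[CROP] == 0.5

    def test_generated_raster_normalized(self, mixed_raster):
        assert abs(composition_proportions(mixed_raster).sum() - 1) < 1e-12


class TestDistributionStats:
    def test_square_patch_has_minimal_shape_index(self):
        grid = np.full((6, 6), CROP)
        grid[1:5, 1:5] = GRASS
        pm = label_patches(LandscapeRaster(grid))
        idx = int(np.nonzero(pm.patch_class == GRASS)[0][0])
        from invadescape.metrics import patch_shape_index, patch_contiguity
        assert patch_shape_index(pm)[idx] == 1.0

    def test_single_cell_patch_contiguity_is_zero(self):
        grid = np.full((5, 5), CROP)
        grid[2, 2] = GRASS
        pm = label_patches(LandscapeRaster(grid))
        from invadescape.metrics import patch_contiguity
        idx = int(np.nonzero(pm.patch_class == GRASS)[0][0])
        assert patch_contiguity(pm)[idx] == 0.0

    def test_strip_patch_perimeter_area_ratio_by_hand(self):
        # 1x4 strip: hand count gives 10 cell edges; cell = 30 m
        grid = np.full((3, 6), CROP)
        grid[1, 1:5] = GRASS
        pm = label_patches(LandscapeRaster(grid))
        idx = int(np.nonzero(pm.patch_class == GRASS)[0][0])
        from invadescape.metrics import patch_para
        expected = (10 * 30) / (4 * 30 * 30)
        assert patch_para(pm)[idx] == pytest.approx(expected)

    def test_two_identical_patches_have_zero_sd(self):
        # whole raster = exactly two congruent patches
        grid = np.full((4, 8), CROP)
        grid[:, :4] = GRASS
        pm = label_patches(LandscapeRaster(grid))
        am, md, sd = patch_distribution_stats(pm, "area")
        assert sd == 0.0
        assert am == md

    def test_unknown_quantity_rejected(self, uniform_grass):
        with pytest.raises(ConfigurationError):
            patch_distribution_stats(label_patches(uniform_grass), "volume")


class TestAggregation:
    def test_uniform_raster_maximally_aggregated(self, uniform_grass):
        agg = aggregation_metrics(uniform_grass)
        assert agg["percentage_like_adjacencies"] == 100.0
        assert agg["aggregation_index"] == 100.0
        assert agg["contagion"] == 100.0  # single-class convention

    def test_checkerboard_has_no_like_adjacencies(self, checkerboard):
        agg = aggregation_metrics(checkerboard)
        assert agg["percentage_like_adjacencies"] == 0.0

    def test_contagion_matches_direct_formula(self):
        grid = np.full((8, 8), GRASS)
        grid[:, 4:] = CROP
        raster = LandscapeRaster(grid)
        fast = aggregation_metrics(raster)["contagion"]
        oracle = oracle_metric_vector(raster)[METRIC_NAMES.index("contag")]
        assert fast == pytest.approx(oracle, abs=1e-9)


class TestDiversity:
    def test_two_equal_classes(self, half_and_half):
        div = diversity_metrics(half_and_half)
        assert div["shannon_diversity"] == pytest.approx(math.log(2))
        assert div["simpson_diversity"] == pytest.approx(0.5)
        assert div["shannon_evenness"] == pytest.approx(1.0)
        assert div["simpson_evenness"] == pytest.approx(1.0)

    def test_single_class_is_zero_by_convention(self, uniform_grass):
        div = diversity_metrics(uniform_grass)
        assert div["shannon_diversity"] == 0.0
        assert div["simpson_diversity"] == 0.0
        assert div["shannon_evenness"] == 0.0

    def test_hand_computed_three_class_shannon(self):
        grid = np.full((10, 10), GRASS)
        grid[:2, :] = CROP           # 0.2
        grid[2, :] = habitat.WATER   # 0.1
        div = diversity_metrics(LandscapeRaster(grid))
        expected = -(0.7 * math.log(0.7) + 0.2 * math.log(0.2)
                     + 0.1 * math.log(0.1))
        assert div["shannon_diversity"] == pytest.approx(expected)


class TestMetricVector:
    def test_has_50_entries_11_composition(self, mixed_raster):
        mv = compute_metric_vector(mixed_raster)
        assert len(mv.values) == 50
        assert len(METRIC_NAMES) == 50
        comp = mv.values[:11]
        assert comp.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_raster_limits(self, uniform_grass):
        mv = compute_metric_vector(uniform_grass)
        assert mv["np"] == 1.0
        assert mv["lpi"] == 100.0
        assert mv["te"] == 0.0
        assert mv["ed"] == 0.0
        assert "enn_am" in mv.flags  # no same-class pair -> imputed
        assert "pafrac" in mv.flags

    def test_oracle_equivalence_on_fixture(self):
        grid = np.full((16, 16), GRASS)
        grid[4:12, 2:9] = CROP
        grid[0:3, 10:16] = CROP
        raster = LandscapeRaster(grid)
        fast = compute_metric_vector(raster).values
        slow = oracle_metric_vector(raster)
        np.testing.assert_allclose(fast, slow, atol=1e-9, rtol=0)

    def test_permutation_invariance_of_structure_metrics(self, mixed_raster):
        """Relabeling classes by a bijection permutes composition but leaves
        class-agnostic structure metrics unchanged."""
        perm = np.roll(np.arange(11), 3)
        permuted = LandscapeRaster(perm[mixed_raster.grid],
                                   mixed_raster.cell_size_m)
        a = compute_metric_vector(mixed_raster)
        b = compute_metric_vector(permuted)
        np.testing.assert_allclose(
            np.sort(a.values[:11]), np.sort(b.values[:11]), atol=1e-12)
        for name in ("np", "te", "ed", "shdi", "contag", "pladj", "ai"):
            assert a[name] == pytest.approx(b[name], abs=1e-9)

    def test_cell_size_scaling(self, mixed_raster):
        """PD and ED respect the physical cell size; proportions do not."""
        small = LandscapeRaster(mixed_raster.grid, cell_size_m=15.0)
        a = compute_metric_vector(mixed_raster)  # 30 m cells
        b = compute_metric_vector(small)
        np.testing.assert_allclose(a.values[:11], b.values[:11])
        assert b["pd"] == pytest.approx(4 * a["pd"])
        assert b["ed"] == pytest.approx(2 * a["ed"])
        assert b["area_am"] == pytest.approx(a["area_am"] / 4)
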