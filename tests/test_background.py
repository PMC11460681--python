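import numpy as np
import pandas as pd
import pytest

from thermoniche.background import (
    AccessibleArea,
    accessible_area,
    build_bias_mask,
    sample_background,
    thermal_breadth_check,
)
from thermoniche.filtering import CellCentroidSet, thin_to_centroids
from thermoniche.grid import RasterGrid
from thermoniche.synthetic import BiasMask


def _centroids(grid, lons, lats):
    return thin_to_centroids(pd.DataFrame({"lon": lons, "lat": lats}), grid)


@pytest.fixture
def occ_centroids(small_world, small_records):
    return thin_to_centroids(small_records, small_world.template)


class TestAccessibleArea:
    def test_selection_includes_adjacent_ecoregions(self, small_world, small_ecoregions):
        # a single centroid with a tiny buffer selects its own ecoregion + neighbors
        grid = small_world.template
        lon, lat = grid.centroid(20, 20)
        cent = _centroids(grid, [lon], [lat])
        area = accessible_area(cent, small_ecoregions, small_world.land, buffer_km=1.0)
        home = small_ecoregions.labels[20, 20]
        assert home in area.ecoregion_ids
        assert small_ecoregions.adjacency[home] <= area.ecoregion_ids

    def test_buffer_reaches_across_border(self, small_world, small_ecoregions):
        # 200 km spans ~2 degrees: a centroid selects ecoregions it does not sit in
        grid = small_world.template
        lon, lat = grid.centroid(20, 20)
        cent = _centroids(grid, [lon], [lat])
        small_buffer = accessible_area(cent, small_ecoregions, small_world.land, buffer_km=1.0)
        big_buffer = accessible_area(cent, small_ecoregions, small_world.land, buffer_km=200.0)
        assert small_buffer.ecoregion_ids < big_buffer.ecoregion_ids

    def test_buffer_monotonicity(self, small_world, small_ecoregions, occ_centroids):
        sizes = [
            len(
                accessible_area(
                    occ_centroids, small_ecoregions, small_world.land, buffer_km=km
                ).ecoregion_ids
            )
            for km in (1, 50, 200)
        ]
        assert sizes == sorted(sizes)

    def test_eligible_cells_are_land(self, small_world, small_ecoregions, occ_centroids):
        area = accessible_area(occ_centroids, small_ecoregions, small_world.land)
        assert not np.any(area.eligible & ~small_world.land)

    def test_no_centroids_rejected(self, small_world, small_ecoregions):
        empty = CellCentroidSet(
            pd.DataFrame(columns=["cell_id", "lon", "lat", "label"]), small_world.template
        )
        with pytest.raises(ValueError, match="no occurrence centroids"):
            accessible_area(empty, small_ecoregions, small_world.land)


class TestBiasMask:
    def test_tallies_become_proportions(self):
        grid = RasterGrid("t", (0, 0), 1.0, np.zeros((1, 3)))
        area = AccessibleArea({0}, np.ones((1, 3), dtype=bool), grid)
        mask = build_bias_mask(np.array([[3.0, 1.0, 0.0]]), area)
        np.testing.assert_allclose(mask.weights, [[0.75, 0.25, 0.0]])

    def test_all_zero_tallies_uniform_fallback(self):
        grid = RasterGrid("t", (0, 0), 1.0, np.zeros((2, 2)))
        eligible = np.array([[True, True], [True, False]])
        area = AccessibleArea({0}, eligible, grid)
        mask = build_bias_mask(np.zeros((2, 2)), area)
        np.testing.assert_allclose(mask.weights[eligible], 1 / 3)

    def test_weights_sum_to_one(self, small_world, small_ecoregions, small_bias, occ_centroids):
        area = accessible_area(occ_centroids, small_ecoregions, small_world.land)
        mask = build_bias_mask(small_bias.weights, area)
        assert mask.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_tallies_rejected(self):
        grid = RasterGrid("t", (0, 0), 1.0, np.zeros((1, 2)))
        area = AccessibleArea({0}, np.ones((1, 2), dtype=bool), grid)
        with pytest.raises(ValueError):
            build_bias_mask(np.array([[-1.0, 2.0]]), area)


class TestSampleBackground:
    def test_contracts(self, small_world, small_ecoregions, small_bias, occ_centroids):
        area = accessible_area(occ_centroids, small_ecoregions, small_world.land)
        mask = build_bias_mask(small_bias.weights, area)
        out = sample_background(area, mask, occ_centroids, seed=5)
        assert len(out) == 2 * len(occ_centroids)
        assert len(np.unique(out.cell_ids)) == len(out)  # without replacement
        assert not set(out.cell_ids) & set(occ_centroids.cell_ids)
        i, j = small_world.template.id_to_index(out.cell_ids)
        assert area.eligible[i, j].all()

    def test_fixed_seed_replays_exactly(self, small_world, small_ecoregions, small_bias, occ_centroids):
        area = accessible_area(occ_centroids, small_ecoregions, small_world.land)
        mask = build_bias_mask(small_bias.weights, area)
        a = sample_background(area, mask, occ_centroids, seed=5)
        b = sample_background(area, mask, occ_centroids, seed=5)
        np.testing.assert_array_equal(a.cell_ids, b.cell_ids)

    def test_inclusion_frequencies_match_sequential_oracle(self):
        # small exactly-checkable setting: draw 3 of 7 weighted cells
        grid = RasterGrid("t", (0, 0), 1.0, np.zeros((1, 7)))
        eligible = np.ones((1, 7), dtype=bool)
        area = AccessibleArea({0}, eligible, grid)
        weights = np.array([[0.30, 0.22, 0.18, 0.12, 0.09, 0.06, 0.03]])
        mask = BiasMask(weights)
        # one occurrence cell (id 6) is excluded from the candidate pool
        occ = CellCentroidSet(
            pd.DataFrame({"cell_id": [6], "lon": [6.5], "lat": [0.5], "label": [1]}), grid
        )
        w_eff = weights.copy()
        w_eff[0, 6] = 0.0

        n_rep, n_draw = 2000, 3
        counts = np.zeros(7)
        for r in range(n_rep):
            out = sample_background(area, mask, occ, seed=1000 + r, ratio=n_draw)
            counts[out.cell_ids] += 1

        rng = np.random.default_rng(99)
        oracle = np.zeros(7)
        probs = w_eff.ravel() / w_eff.sum()
        for _ in range(n_rep):
            p = probs.copy()
            for _ in range(n_draw):
                k = rng.choice(7, p=p / p.sum())
                oracle[k] += 1
                p[k] = 0.0
        tv = 0.5 * np.abs(counts / (n_rep * n_draw) - oracle / (n_rep * n_draw)).sum()
        assert tv < 0.02

    def test_insufficient_cells_fail_with_deficit(self):
        grid = RasterGrid("t", (0, 0), 1.0, np.zeros((1, 4)))
        area = AccessibleArea({0}, np.ones((1, 4), dtype=bool), grid)
        mask = BiasMask(np.full((1, 4), 0.25))
        occ = CellCentroidSet(
            pd.DataFrame({"cell_id": [0, 1], "lon": [0.5, 1.5], "lat": [0.5, 0.5], "label": 1}),
            grid,
        )
        with pytest.raises(ValueError, match="deficit"):
            sample_background(area, mask, occ, seed=0)


class TestBreadthCheck:
    def test_wider_background_passes(self):
        assert thermal_breadth_check([5, 35], [0, 40]).passed

    def test_narrow_background_warns_both_tails(self):
        rep = thermal_breadth_check([5, 35], [10, 30])
        assert not rep.passed
        assert len(rep.messages) == 2

    def test_equal_ranges_pass(self):
        assert thermal_breadth_check([5, 35], [5, 35]).passed

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            thermal_breadth_check([], [1, 2])
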