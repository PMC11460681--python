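import numpy as np
import pandas as pd
import pytest

from thermoniche import (
    SyntheticWorldConfig,
    TrueSuitability,
    generate_bias_surface,
    generate_ecoregions,
    generate_trait_posteriors,
    generate_world,
    sample_occurrences,
    true_suitability,
)
from thermoniche.mechanistic import BriereParams, QuadraticParams
from thermoniche.synthetic import (
    default_trait_truth,
    trait_posterior_from_csv,
    trait_posterior_to_csv,
)


class TestWorld:
    def test_same_seed_bit_identical(self, small_config, small_world):
        again = generate_world(small_config)
        for name, g in small_world.grids.items():
            np.testing.assert_array_equal(g.values, again.grids[name].values)
        np.testing.assert_array_equal(small_world.land, again.land)

    def test_temperature_spans_thermal_limits(self, small_world):
        t = small_world.config.truth
        temp = small_world.temperature
        assert temp.min() < t.tmin - 5
        assert temp.max() > t.tmax + 5

    def test_covariates_pass_correlation_screen(self, small_world):
        table = small_world.covariate_table()
        corr = table.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() < 0.8

    def test_too_small_extent_rejected(self):
        cfg = SyntheticWorldConfig(extent=(0.0, 40.0, 0.3, 40.3))
        with pytest.raises(ValueError, match="too small"):
            generate_world(cfg)


class TestSuitability:
    def test_zero_at_limits_and_peak_at_optimum(self):
        p = TrueSuitability(12, 27, 36, peak_prob=0.9)
        assert true_suitability(12.0, p) == 0.0
        assert true_suitability(36.0, p) == 0.0
        assert true_suitability(40.0, p) == 0.0
        assert true_suitability(27.0, p) == pytest.approx(0.9, abs=1e-12)

    def test_dense_grid_argmax_at_topt(self):
        p = TrueSuitability(12, 27, 36)
        grid = np.arange(12, 36, 0.01)
        argmax = grid[np.argmax(true_suitability(grid, p))]
        assert abs(argmax - 27.0) <= 0.01

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            TrueSuitability(27, 12, 36)


class TestOccurrences:
    def test_no_occurrences_below_thermal_minimum(self, small_world, small_records):
        truth = small_world.config.truth
        i, j = small_world.template.cell_index(
            small_records["lon"].to_numpy(), small_records["lat"].to_numpy()
        )
        assert small_world.temperature[i, j].min() > truth.tmin

    def test_fixed_seed_reproducible(self, small_world, small_bias, small_records):
        again = sample_occurrences(small_world, bias=small_bias)
        pd.testing.assert_frame_equal(small_records, again)

    def test_occupancy_matches_theoretical_probabilities(self):
        # Monte-Carlo check on a coarse world so multinomial noise is small
        # relative to the per-cell probabilities at n = 50,000
        cfg = SyntheticWorldConfig(
            seed=21, extent=(0.0, 40.0, 1.2, 41.2), cell_size=0.1, n_occurrences=10
        )
        world = generate_world(cfg)
        bias = generate_bias_surface(world)
        n = 50_000
        occ = sample_occurrences(world, n=n, bias=bias, seed=77, violation_fraction=0.0)
        i, j = world.template.cell_index(occ["lon"].to_numpy(), occ["lat"].to_numpy())
        counts = np.zeros(world.land.size)
        np.add.at(counts, world.template.cell_id(i, j), 1)
        suit = true_suitability(world.temperature, cfg.truth)
        w = suit * bias.weights
        w[~world.land] = 0
        p = (w / w.sum()).ravel()
        tv = 0.5 * np.abs(counts / n - p).sum()
        assert tv < 0.02

    def test_all_zero_probability_fails(self, small_world, small_bias):
        scorched = TrueSuitability(100, 110, 120)  # hotter than any cell
        with pytest.raises(ValueError, match="all-zero"):
            sample_occurrences(small_world, params=scorched, bias=small_bias)


class TestEcoregions:
    def test_every_cell_maps_to_exactly_one_ecoregion(self, small_world, small_ecoregions):
        labels = small_ecoregions.labels
        assert labels.shape == small_world.land.shape
        assert set(np.unique(labels)) <= set(small_ecoregions.polygons)

    def test_polygons_tessellate_extent(self, small_world, small_ecoregions):
        from shapely.geometry import box
        from shapely.ops import unary_union

        lon0, lat0, lon1, lat1 = small_world.config.extent
        union = unary_union(list(small_ecoregions.polygons.values()))
        assert union.area == pytest.approx((lon1 - lon0) * (lat1 - lat0), rel=1e-6)
        areas = sum(p.area for p in small_ecoregions.polygons.values())
        assert areas == pytest.approx(union.area, rel=1e-6)  # interiors disjoint

    def test_two_ecoregions_are_mutual_neighbors(self, small_world):
        eco = generate_ecoregions(small_world, n_ecoregions=2, seed=4)
        assert eco.adjacency == {0: {1}, 1: {0}}

    def test_geojson_roundtrip(self, small_ecoregions, tmp_path):
        from thermoniche.synthetic import ecoregions_from_geojson

        path = tmp_path / "eco.geojson"
        small_ecoregions.to_geojson(path)
        polys, adj = ecoregions_from_geojson(path)
        assert set(polys) == set(small_ecoregions.polygons)
        assert adj == small_ecoregions.adjacency


class TestBias:
    def test_weights_normalized_and_on_land(self, small_world, small_bias):
        assert small_bias.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert (small_bias.weights[~small_world.land] == 0).all()

    def test_small_concentration_near_uniform(self, small_world):
        bias = generate_bias_surface(small_world, concentration=0.05, seed=3)
        w = bias.weights[small_world.land]
        assert w.max() / w.min() < 1.5

    def test_fixed_seed_reproducible(self, small_world):
        a = generate_bias_surface(small_world, seed=9)
        b = generate_bias_surface(small_world, seed=9)
        np.testing.assert_array_equal(a.weights, b.weights)


class TestTraitPosteriors:
    def test_zero_dispersion_collapses_to_truth(self):
        truth = default_trait_truth()
        post = generate_trait_posteriors(truth, n_draws=10, dispersion=0.0, seed=1)
        assert all(p == truth["MDR"] for p in post.draws["MDR"])
        assert all(p == truth["mu"] for p in post.draws["mu"])

    def test_draw_means_converge_to_truth(self):
        truth = default_trait_truth()
        n = 5000
        disp = 0.02
        post = generate_trait_posteriors(truth, n_draws=n, dispersion=disp, seed=2)
        t0 = np.array([p.T0 for p in post.draws["MDR"]])
        se = disp * 10 / np.sqrt(n)
        assert abs(t0.mean() - truth["MDR"].T0) < 3 * se
        c = np.array([p.c for p in post.draws["MDR"]])
        assert abs(c.mean() - truth["MDR"].c) < 3 * disp * truth["MDR"].c / np.sqrt(n)

    def test_draws_respect_validity(self):
        truth = default_trait_truth()
        post = generate_trait_posteriors(truth, n_draws=500, dispersion=0.2, seed=3)
        for plist in post.draws.values():
            assert all(p.T0 < p.Tm for p in plist)

    def test_csv_roundtrip(self, tmp_path):
        post = generate_trait_posteriors(default_trait_truth(), n_draws=5, dispersion=0.05, seed=4)
        path = tmp_path / "draws.csv"
        trait_posterior_to_csv(post, path)
        back = trait_posterior_from_csv(path)
        assert back.n_draws == 5
        for trait in post.draws:
            for a, b in zip(post.draws[trait], back.draws[trait]):
                assert a.T0 == pytest.approx(b.T0)
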