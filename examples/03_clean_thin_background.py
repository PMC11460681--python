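"""Record cleaning, spatial thinning, and bias-weighted background sampling.

Raw presence records are filtered by the cleaning cascade (basis of record,
coordinate uncertainty/precision, land, covariates, activity season), thinned
to unique cell centroids, and matched with twice as many pseudo-absence
cells drawn from the ecoregion-based accessible area, weighted by sampling
effort.
"""

from thermoniche import (
    SyntheticWorldConfig,
    accessible_area,
    build_bias_mask,
    filter_records,
    generate_bias_surface,
    generate_ecoregions,
    generate_world,
    sample_background,
    sample_occurrences,
    thermal_breadth_check,
    thin_to_centroids,
)
from thermoniche.filtering import attach_covariates

config = SyntheticWorldConfig(seed=2)
world = generate_world(config)
eco = generate_ecoregions(world)
bias = generate_bias_surface(world)
records = sample_occurrences(world, bias=bias)

result = filter_records(records, world.grids, world.land, study_period=config.study_period)
print(f"{len(records)} raw records -> {len(result.survivors)} survivors")
print("rejections by rule:", {k: v for k, v in result.tally.items() if v})

centroids = thin_to_centroids(result.survivors, world.template)
centroids, _ = attach_covariates(centroids, world.grids)
print(f"thinned to {len(centroids)} unique occupied cells")

area = accessible_area(centroids, eco, world.land, buffer_km=200)
mask = build_bias_mask(bias.weights, area)
background = sample_background(area, mask, centroids, seed=config.seed)
background, _ = attach_covariates(background, world.grids)
print(f"accessible area: {len(area.ecoregion_ids)} ecoregions, "
      f"{area.n_eligible} eligible cells")
print(f"background: {len(background)} cells (2x occurrence centroids)")

breadth = thermal_breadth_check(
    centroids.table["temperature_mean"], background.table["temperature_mean"]
)
print(f"thermal breadth check: {'pass' if breadth.passed else 'WARN'} "
      f"(occ {breadth.occ_range[0]:.1f}..{breadth.occ_range[1]:.1f} C, "
      f"bg {breadth.bg_range[0]:.1f}..{breadth.bg_range[1]:.1f} C)")
# A background narrower than the occurrences could not inform thermal limits.
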