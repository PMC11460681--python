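"""Lab-vs-field comparison and the end-to-end synthetic study driver.

The scientific question: do thermal limits measured on mosquitoes in the
laboratory transport to the field?  Lab-side extrema come from the
mechanistic abundance curve M(T); field-side extrema come from partial
dependence curves of occurrence models.  Both curve families are min-max
scaled to [0, 1] for display, and the median extrema are correlated across
species with Pearson's r (pairwise deletion for species missing one side).

``run_species_pipeline`` wires every stage together on a synthetic world —
generation, cleaning, thinning, accessible-area background sampling, model
fitting, interpretation — and ``run_study`` repeats it across species and
adds the mechanistic side and the correlations.  A region-exclusion refit
(dropping occurrences and background candidates inside given lon/lat boxes)
supports sensitivity analyses against geographically uneven sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import background as bg
from . import filtering, interpret, mechanistic, sdm, synthetic


def scale_unit_interval(values) -> np.ndarray:
    """(v - min) / (max - min); a constant input maps to zeros with a warning."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to scale")
    span = v.max() - v.min()
    if span == 0:
        warnings.warn("constant curve: scaled values set to 0")
        return np.zeros_like(v)
    return (v - v.min()) / span


def pearson_r(x, y) -> float:
    """Product-moment correlation with explicit degenerate-input errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("sequences must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0:
        raise ValueError("zero variance in x")
    if np.std(y) == 0:
        raise ValueError("zero variance in y")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class SpeciesExtremaPair:
    """Median thermal extrema for one species from both approaches."""

    species: str
    field_tmin: float | None
    field_topt: float | None
    lab_tmin: float | None
    lab_topt: float | None
    activity_mode: str = "year_round"
    field_ranges: dict = field(default_factory=dict)  # min-max over bootstrap iterations
    lab_ci: dict = field(default_factory=dict)  # 95% CI over posterior draws


def compare_lab_field(pairs: list[SpeciesExtremaPair]) -> dict:
    """Pearson r of median lab vs field extrema, plus per-species differences.

    Species missing one side of a quantity are excluded pairwise for that
    quantity only; fewer than 3 complete pairs raises for that quantity.
    Differences are lab minus field, in degC.
    """
    report: dict = {"species": {}, "correlations": {}, "n_excluded": {}}
    for p in sorted(pairs, key=lambda q: q.species):
        report["species"][p.species] = {
            "field": {"tmin": p.field_tmin, "topt": p.field_topt, "ranges": p.field_ranges},
            "lab": {"tmin": p.lab_tmin, "topt": p.lab_topt, "ci": p.lab_ci},
            "difference_lab_minus_field": {
                "tmin": None
                if p.lab_tmin is None or p.field_tmin is None
                else p.lab_tmin - p.field_tmin,
                "topt": None
                if p.lab_topt is None or p.field_topt is None
                else p.lab_topt - p.field_topt,
            },
        }
    for quantity, lab_attr, field_attr in (
        ("tmin", "lab_tmin", "field_tmin"),
        ("topt", "lab_topt", "field_topt"),
    ):
        complete = [
            (getattr(p, lab_attr), getattr(p, field_attr))
            for p in pairs
            if getattr(p, lab_attr) is not None and getattr(p, field_attr) is not None
        ]
        report["n_excluded"][quantity] = len(pairs) - len(complete)
        if len(complete) < 3:
            raise ValueError(
                f"fewer than 3 species with both lab and field {quantity} defined"
            )
        lab_vals, field_vals = zip(*complete)
        report["correlations"][quantity] = pearson_r(lab_vals, field_vals)
    return report


# ---------------------------------------------------------------------------
# end-to-end synthetic pipeline


@dataclass
class SpeciesPipelineResult:
    species: str
    truth: synthetic.TrueSuitability
    n_raw: int
    n_centroids: int
    n_background: int
    screen: sdm.ScreenReport
    breadth: bg.BreadthReport
    bundle: sdm.FittedModelBundle
    extrema: interpret.FieldExtrema
    filter_tally: dict


def run_species_pipeline(
    config: synthetic.SyntheticWorldConfig,
    n_bootstrap: int = 5,
    space: sdm.HyperparameterSpace | None = None,
    species: str = "Synthetica exemplaris",
    exclusion_boxes: list | None = None,
    pdp_points: int = interpret.DEFAULT_PDP_POINTS,
) -> SpeciesPipelineResult:
    """World generation through field thermal extrema, for one species.

    ``exclusion_boxes`` — optional (lon0, lat0, lon1, lat1) boxes whose
    occurrences and background candidate cells are dropped before fitting
    (region-exclusion sensitivity refit); the generating world and seeds are
    untouched, so an empty list reproduces the baseline run exactly.
    """
    space = space or sdm.desk_space()
    world = synthetic.generate_world(config)
    eco = synthetic.generate_ecoregions(world)
    bias = synthetic.generate_bias_surface(world)
    records = synthetic.sample_occurrences(world, bias=bias, species=species)

    exclusion_mask = np.zeros(world.land.shape, dtype=bool)
    if exclusion_boxes:
        lon_c, lat_c = world.template.centroid_grids()
        for lon0, lat0, lon1, lat1 in exclusion_boxes:
            exclusion_mask |= (
                (lon_c >= lon0) & (lon_c < lon1) & (lat_c >= lat0) & (lat_c < lat1)
            )
        keep = np.ones(len(records), dtype=bool)
        for lon0, lat0, lon1, lat1 in exclusion_boxes:
            keep &= ~(
                records["lon"].between(lon0, lon1).to_numpy()
                & records["lat"].between(lat0, lat1).to_numpy()
            )
        records = records[keep].reset_index(drop=True)
        if len(records) < 30:
            raise ValueError(
                f"region exclusion leaves only {len(records)} occurrences"
            )

    filt = filtering.filter_records(
        records, world.grids, world.land, study_period=config.study_period
    )
    centroids = filtering.thin_to_centroids(filt.survivors, world.template)
    centroids, _ = filtering.attach_covariates(centroids, world.grids)

    area = bg.accessible_area(centroids, eco, world.land & ~exclusion_mask)
    bias_mask = bg.build_bias_mask(bias.weights, area)
    background = bg.sample_background(area, bias_mask, centroids, seed=config.seed + 3571)
    background, _ = filtering.attach_covariates(background, world.grids)

    table = pd.concat([centroids.table, background.table], ignore_index=True)
    screen = sdm.screen_covariates(table)
    breadth = bg.thermal_breadth_check(
        centroids.table["temperature_mean"], background.table["temperature_mean"]
    )
    bundle = sdm.bootstrap_models(table, n_iterations=n_bootstrap, seed=config.seed, space=space)
    extrema = interpret.field_thermal_extrema(bundle, "temperature_mean", n_points=pdp_points)
    return SpeciesPipelineResult(
        species=species,
        truth=config.truth,
        n_raw=len(records),
        n_centroids=len(centroids),
        n_background=len(background),
        screen=screen,
        breadth=breadth,
        bundle=bundle,
        extrema=extrema,
        filter_tally=filt.tally,
    )


def region_exclusion_refit(
    config: synthetic.SyntheticWorldConfig,
    exclusion_boxes: list,
    n_bootstrap: int = 5,
    space: sdm.HyperparameterSpace | None = None,
    species: str = "Synthetica exemplaris",
) -> SpeciesPipelineResult:
    """Re-run the full pipeline with the given regions excluded."""
    return run_species_pipeline(
        config,
        n_bootstrap=n_bootstrap,
        space=space,
        species=species,
        exclusion_boxes=exclusion_boxes,
    )


# ---------------------------------------------------------------------------
# multi-species study


@dataclass
class SpeciesSpec:
    """One synthetic species: shared truth for the lab and field sides."""

    name: str
    tmin: float
    tmax: float
    trait_truth: dict = field(init=False)
    topt: float = field(init=False)

    def __post_init__(self) -> None:
        self.trait_truth = synthetic.default_trait_truth(self.tmin, self.tmax)
        fine = np.arange(self.tmin - 1, self.tmax + 1, 0.001)
        curve = mechanistic.abundance_curve(
            mechanistic.TraitPosterior.from_point(self.trait_truth), fine
        )
        self.topt = float(fine[int(np.argmax(curve.values[0]))])


DEFAULT_SPECIES = (
    SpeciesSpec("Synthetica frigida", 6.0, 32.0),
    SpeciesSpec("Synthetica media", 10.0, 35.0),
    SpeciesSpec("Synthetica calida", 14.0, 38.0),
    SpeciesSpec("Synthetica torrida", 17.0, 40.0),
)


def run_study(
    species_specs=DEFAULT_SPECIES,
    seed: int = 0,
    n_bootstrap: int = 5,
    n_draws: int = 1000,
    dispersion: float = 0.02,
    base_config: synthetic.SyntheticWorldConfig | None = None,
    space: sdm.HyperparameterSpace | None = None,
) -> dict:
    """Full lab-vs-field study across synthetic species.

    Per species: a synthetic world generated from its shared thermal truth,
    the occurrence->background->model->PDP pipeline for the field side, and
    pseudo-posterior trait draws composed into M(T) for the lab side.
    Returns the comparison report plus per-species diagnostics.
    """
    base = base_config or synthetic.SyntheticWorldConfig()
    pairs = []
    diagnostics = {}
    for k, spec in enumerate(species_specs):
        truth = synthetic.TrueSuitability(spec.tmin, spec.topt, spec.tmax)
        config = replace(base, seed=int(seed) + 1000 * k, truth=truth)
        result = run_species_pipeline(
            config, n_bootstrap=n_bootstrap, space=space, species=spec.name
        )
        posterior = synthetic.generate_trait_posteriors(
            spec.trait_truth, n_draws=n_draws, dispersion=dispersion, seed=int(seed) + 77 * k
        )
        curve = mechanistic.abundance_curve(posterior)
        lab = mechanistic.posterior_summary(curve)
        fe = result.extrema
        pairs.append(
            SpeciesExtremaPair(
                species=spec.name,
                field_tmin=None if fe.tmin is None else fe.tmin.median,
                field_topt=None if fe.topt is None else fe.topt.median,
                lab_tmin=lab.summary["Tmin"]["median"],
                lab_topt=lab.summary["Topt"]["median"],
                field_ranges={
                    "tmin": None if fe.tmin is None else (fe.tmin.minimum, fe.tmin.maximum),
                    "topt": None if fe.topt is None else (fe.topt.minimum, fe.topt.maximum),
                },
                lab_ci={
                    "tmin": (lab.summary["Tmin"]["lower"], lab.summary["Tmin"]["upper"]),
                    "topt": (lab.summary["Topt"]["lower"], lab.summary["Topt"]["upper"]),
                },
            )
        )
        diagnostics[spec.name] = {
            "truth": {"tmin": truth.tmin, "topt": truth.topt, "tmax": truth.tmax},
            "n_centroids": result.n_centroids,
            "n_background": result.n_background,
            "eval_auc_median": float(np.median(result.bundle.eval_aucs)),
            "breadth_pass": result.breadth.passed,
            "field_tmin_steepest": None
            if fe.tmin_steepest is None
            else fe.tmin_steepest.median,
        }
    report = compare_lab_field(pairs)
    report["diagnostics"] = diagnostics
    # alternative lower-limit rule: steepest-derivative Tmin vs the lab medians
    alt = [
        (diagnostics[p.species]["field_tmin_steepest"], p.lab_tmin)
        for p in pairs
        if diagnostics[p.species]["field_tmin_steepest"] is not None and p.lab_tmin is not None
    ]
    if len(alt) >= 3:
        f, l = zip(*alt)
        report["correlations"]["tmin_steepest"] = pearson_r(l, f)
    return report
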