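"""Synthetic world generation with known ground-truth thermal response.

Real studies of this kind consume crowd-sourced occurrence databases,
satellite covariate stacks, and published ecoregion polygons.  None of that
is reproducible at desk scale, so this module builds a fully specified
stand-in world: a smooth temperature field with a latitudinal gradient,
auxiliary covariates with controlled correlation to temperature, a land/ocean
mask, a Voronoi ecoregion tessellation, a spatially clustered
sampling-effort (bias) surface, presence-only occurrence records drawn from a
known unimodal thermal suitability, and pseudo-posterior trait parameter
draws around known true values.  Because the generating truth is known,
every downstream stage admits parameter-recovery tests.

The ground-truth suitability is a generalized Briere curve

    s(T) = peak_prob * T*(T - Tmin)*(Tmax - T)^m / norm,
    m = (Tmax - Topt) * (1/Topt + 1/(Topt - Tmin)),

which is zero outside (Tmin, Tmax), strictly positive inside, and attains its
maximum ``peak_prob`` exactly at Topt (the exponent solves the stationarity
condition in closed form) — an asymmetric shape matching mosquito trait
biology with closed-form zeroes and peak.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Point, box, mapping, shape
from shapely.ops import voronoi_diagram

from .grid import RasterGrid
from .mechanistic import BriereParams, QuadraticParams, TraitPosterior

OCCURRENCE_COLUMNS = [
    "species",
    "lon",
    "lat",
    "date",
    "coord_uncertainty_m",
    "basis_of_record",
    "coord_decimals",
]

#: Injected record defects cycled through when ``violation_fraction`` > 0.
VIOLATION_TYPES = (
    "fossil",
    "unknown_basis",
    "high_uncertainty",
    "low_precision",
    "out_of_period",
)


@dataclass(frozen=True)
class TrueSuitability:
    """Known unimodal thermal suitability: zero outside (tmin, tmax), peak at topt."""

    tmin: float = 12.0
    topt: float = 27.0
    tmax: float = 36.0
    peak_prob: float = 0.9

    def __post_init__(self) -> None:
        if not self.tmin < self.topt < self.tmax:
            raise ValueError("require Tmin < Topt < Tmax")
        if self.topt <= 0:
            raise ValueError("the Briere-form truth needs Topt > 0 degC")
        if not 0 < self.peak_prob <= 1:
            raise ValueError("peak_prob must be in (0, 1]")

    @property
    def shape_exponent(self) -> float:
        # d/dT log[T (T-Tmin) (Tmax-T)^m] = 0 at Topt
        return (self.tmax - self.topt) * (1.0 / self.topt + 1.0 / (self.topt - self.tmin))


def true_suitability(T, params: TrueSuitability):
    """Occurrence probability at temperature T under the generating truth."""
    T = np.asarray(T, dtype=float)
    m = params.shape_exponent
    out = np.zeros_like(T)
    inside = (T > params.tmin) & (T < params.tmax)
    Ti = T[inside]
    raw = Ti * (Ti - params.tmin) * (params.tmax - Ti) ** m
    norm = params.topt * (params.topt - params.tmin) * (params.tmax - params.topt) ** m
    out[inside] = params.peak_prob * np.maximum(raw, 0.0) / norm
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SyntheticWorldConfig:
    seed: int = 0
    extent: tuple[float, float, float, float] = (0.0, 40.0, 3.0, 43.0)  # lon0, lat0, lon1, lat1
    cell_size: float = 0.05
    n_ecoregions: int = 12
    truth: TrueSuitability = field(default_factory=TrueSuitability)
    n_occurrences: int = 1000
    bias_concentration: float = 2.0
    covariate_noise_sd: float = 0.3
    ocean_fraction: float = 0.08
    study_period: tuple[int, int] = (2000, 2019)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_occurrences < 1:
            raise ValueError("n_occurrences must be >= 1")
        if self.bias_concentration <= 0:
            raise ValueError("bias_concentration must be positive")


@dataclass
class SyntheticWorld:
    """Covariate rasters + land mask sharing one grid geometry."""

    config: SyntheticWorldConfig
    grids: dict[str, RasterGrid]
    land: np.ndarray  # boolean (n_rows, n_cols)

    @property
    def template(self) -> RasterGrid:
        return self.grids["temperature_mean"]

    @property
    def temperature(self) -> np.ndarray:
        return self.grids["temperature_mean"].values

    def covariate_table(self) -> pd.DataFrame:
        """One row per land cell, one column per covariate."""
        mask = self.land
        return pd.DataFrame({name: g.values[mask] for name, g in self.grids.items()})


def _bump_field(rng, n_rows, n_cols, n_bumps=18, width_frac=0.22):
    """Smooth random field in [0, 1] from a sum of Gaussian bumps."""
    ii, jj = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    fld = np.zeros((n_rows, n_cols))
    scale = max(n_rows, n_cols) * width_frac
    for _ in range(n_bumps):
        ci = rng.uniform(0, n_rows)
        cj = rng.uniform(0, n_cols)
        w = rng.uniform(0.5, 1.5) * scale
        amp = rng.uniform(0.3, 1.0)
        fld += amp * np.exp(-((ii - ci) ** 2 + (jj - cj) ** 2) / (2 * w**2))
    lo, hi = fld.min(), fld.max()
    return (fld - lo) / (hi - lo) if hi > lo else np.zeros_like(fld)


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Build the covariate stack and land mask for a synthetic study region.

    The temperature field runs hot (Tmax*+6) in the south to cold (Tmin*-6)
    in the north with smooth bounded noise, so the attained range strictly
    contains (Tmin*-5, Tmax*+5) and the thermal extrema are identifiable.
    Auxiliary covariates are constructed with pairwise |r| to temperature
    below the 0.8 screening threshold.
    """
    lon0, lat0, lon1, lat1 = config.extent
    n_cols = int(round((lon1 - lon0) / config.cell_size))
    n_rows = int(round((lat1 - lat0) / config.cell_size))
    if n_rows < 10 or n_cols < 10:
        raise ValueError(
            f"extent too small to hold the requested thermal gradient "
            f"({n_rows}x{n_cols} cells; need at least 10x10)"
        )
    rng = np.random.default_rng(config.seed)
    truth = config.truth

    # temperature: south = hot, north = cold, plus smooth noise bounded to +-0.8
    frac_north = (np.arange(n_rows) + 0.5)[:, None] / n_rows * np.ones((1, n_cols))
    t_hot, t_cold = truth.tmax + 6.0, truth.tmin - 6.0
    noise = (_bump_field(rng, n_rows, n_cols) - 0.5) * 1.6
    temperature = t_hot + (t_cold - t_hot) * frac_north + noise

    # mild latitudinal trend only: seasonal variability must not mirror the
    # mean-temperature gradient or the two fail the collinearity screen
    temp_sd = 2.0 + 0.8 * frac_north + (_bump_field(rng, n_rows, n_cols) - 0.5) * 2.0

    # auxiliary covariates: rho * standardized temperature + independent structure
    z_t = (temperature - temperature.mean()) / temperature.std()
    aux_spec = {
        "evi_mean": (0.45, 0.2, 0.6),
        "precip_dry_quarter": (-0.35, 10.0, 120.0),
        "human_pop_density": (0.15, 0.0, 500.0),
        "forest_cover": (0.0, 5.0, 80.0),
    }
    grids_arr = {"temperature_mean": temperature, "temperature_sd": temp_sd}
    for name, (rho, lo, hi) in aux_spec.items():
        z = (_bump_field(rng, n_rows, n_cols) - 0.5) * 2.0
        z = (z - z.mean()) / max(z.std(), 1e-9)
        mix = rho * z_t + np.sqrt(1 - rho**2) * z
        mix = mix + rng.normal(0, config.covariate_noise_sd, mix.shape)
        lo_m, hi_m = mix.min(), mix.max()
        grids_arr[name] = lo + (hi - lo) * (mix - lo_m) / (hi_m - lo_m)

    land_field = _bump_field(rng, n_rows, n_cols)
    land = land_field > np.quantile(land_field, config.ocean_fraction)

    template = RasterGrid("temperature_mean", (lon0, lat0), config.cell_size, temperature)
    grids = {name: template.like(name, arr) for name, arr in grids_arr.items()}
    grids["temperature_mean"] = template

    land_t = temperature[land]
    if not (land_t.min() < truth.tmin and land_t.max() > truth.topt):
        raise ValueError("land cells do not span temperatures below Tmin* and above Topt*")
    return SyntheticWorld(config, grids, land)


# ---------------------------------------------------------------------------
# ecoregions


@dataclass
class Ecoregions:
    """Voronoi tessellation of the extent into integer-labeled ecoregions."""

    polygons: dict[int, object]  # eco_id -> shapely Polygon
    labels: np.ndarray  # (n_rows, n_cols) eco_id per cell
    adjacency: dict[int, set[int]]  # rook adjacency (shared boundary length > 0)
    seeds: np.ndarray  # (n, 2) lon/lat generator points

    def to_geojson(self, path=None):
        features = [
            {
                "type": "Feature",
                "properties": {"eco_id": int(eid)},
                "geometry": mapping(poly),
            }
            for eid, poly in sorted(self.polygons.items())
        ]
        fc = {"type": "FeatureCollection", "features": features}
        if path is not None:
            with open(path, "w") as fh:
                json.dump(fc, fh)
        return fc


def generate_ecoregions(world: SyntheticWorld, n_ecoregions: int | None = None, seed: int | None = None) -> Ecoregions:
    """Voronoi tessellation from random generator points.

    Every cell belongs to exactly one ecoregion (nearest generator point in
    degree space, which is the Voronoi rule); adjacency is rook (shared
    boundary of positive length).
    """
    cfg = world.config
    n = cfg.n_ecoregions if n_ecoregions is None else n_ecoregions
    if n < 2:
        raise ValueError("need at least 2 ecoregions")
    rng = np.random.default_rng(cfg.seed + 7919 if seed is None else seed)
    lon0, lat0, lon1, lat1 = cfg.extent
    seeds = np.column_stack(
        [rng.uniform(lon0, lon1, n), rng.uniform(lat0, lat1, n)]
    )

    env = box(lon0, lat0, lon1, lat1)
    cells = voronoi_diagram(MultiPoint([Point(p) for p in seeds]), envelope=env)
    tree = cKDTree(seeds)
    polygons: dict[int, object] = {}
    for geom in cells.geoms:
        clipped = geom.intersection(env)
        if clipped.is_empty:
            continue
        _, eid = tree.query([clipped.representative_point().x, clipped.representative_point().y])
        polygons[int(eid)] = clipped
    if len(polygons) != n:
        raise RuntimeError("Voronoi tessellation did not yield one polygon per seed")

    lon_c, lat_c = world.template.centroid_grids()
    _, labels = tree.query(np.column_stack([lon_c.ravel(), lat_c.ravel()]))
    labels = labels.reshape(lon_c.shape).astype(int)

    adjacency: dict[int, set[int]] = {eid: set() for eid in polygons}
    ids = sorted(polygons)
    for a_pos, a in enumerate(ids):
        for b in ids[a_pos + 1 :]:
            if polygons[a].intersection(polygons[b]).length > 1e-9:
                adjacency[a].add(b)
                adjacency[b].add(a)
    return Ecoregions(polygons, labels, adjacency, seeds)


def ecoregions_from_geojson(path_or_obj) -> tuple[dict[int, object], dict[int, set[int]]]:
    """Read polygons + derive rook adjacency from a GeoJSON FeatureCollection."""
    if isinstance(path_or_obj, dict):
        fc = path_or_obj
    else:
        with open(path_or_obj) as fh:
            fc = json.load(fh)
    polygons = {
        int(f["properties"]["eco_id"]): shape(f["geometry"]) for f in fc["features"]
    }
    adjacency: dict[int, set[int]] = {eid: set() for eid in polygons}
    ids = sorted(polygons)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if polygons[a].intersection(polygons[b]).length > 1e-9:
                adjacency[a].add(b)
                adjacency[b].add(a)
    return polygons, adjacency


# ---------------------------------------------------------------------------
# sampling-effort bias


@dataclass
class BiasMask:
    """Per-cell sampling-effort weights; nonnegative, summing to 1 over land."""

    weights: np.ndarray  # (n_rows, n_cols); 0 off-land

    def __post_init__(self) -> None:
        if np.any(self.weights < 0):
            raise ValueError("bias weights must be nonnegative")
        total = self.weights.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"bias weights must sum to 1 (got {total})")


def generate_bias_surface(world: SyntheticWorld, concentration: float | None = None, seed: int | None = None) -> BiasMask:
    """Spatially clustered sampling-effort surface, normalized over land.

    Weights are exp(concentration * g) for a smooth field g in [0, 1]: as
    concentration -> 0 the weights become uniform; larger values concentrate
    effort into hotspots, emulating uneven collection effort.
    """
    cfg = world.config
    c = cfg.bias_concentration if concentration is None else concentration
    if c <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(cfg.seed + 104729 if seed is None else seed)
    g = _bump_field(rng, world.land.shape[0], world.land.shape[1], n_bumps=8, width_frac=0.12)
    w = np.exp(c * g)
    w[~world.land] = 0.0
    return BiasMask(w / w.sum())


# ---------------------------------------------------------------------------
# occurrences


def sample_occurrences(
    world: SyntheticWorld,
    params: TrueSuitability | None = None,
    n: int | None = None,
    bias: BiasMask | None = None,
    seed: int | None = None,
    violation_fraction: float = 0.1,
    species: str = "Synthetica exemplaris",
) -> pd.DataFrame:
    """Presence-only records: cells drawn with p ~ suitability(T) * bias weight.

    A fixed fraction of records is injected with labeled filter-violating
    metadata (fossil/unknown basis, oversized or missing-and-imprecise
    coordinates, out-of-period dates) so cleaning stages have known expected
    survivor counts; the ``injected_violation`` column names the defect ('' =
    clean).
    """
    cfg = world.config
    params = cfg.truth if params is None else params
    n = cfg.n_occurrences if n is None else n
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(cfg.seed + 15485863 if seed is None else seed)

    suit = true_suitability(world.temperature, params)
    w = suit * (bias.weights if bias is not None else world.land.astype(float))
    w[~world.land] = 0.0
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero sampling probability: no land cell is suitable")
    p = (w / total).ravel()
    flat = rng.choice(p.size, size=n, replace=True, p=p)
    i, j = np.divmod(flat, world.template.n_cols)
    lon_c, lat_c = world.template.centroid(i, j)
    d = cfg.cell_size
    lon = lon_c + rng.uniform(-0.5, 0.5, n) * d * 0.98
    lat = lat_c + rng.uniform(-0.5, 0.5, n) * d * 0.98

    y0, y1 = cfg.study_period
    years = rng.integers(y0, y1 + 1, n)
    days = rng.integers(1, 29, n)
    months = rng.integers(1, 13, n)
    dates = [f"{y:04d}-{m:02d}-{dd:02d}" for y, m, dd in zip(years, months, days)]

    # clean metadata: half carry a small stated uncertainty, half rely on precision
    has_unc = rng.random(n) < 0.5
    unc = np.where(has_unc, rng.uniform(10, 900, n), np.nan)
    decimals = np.full(n, 4)
    basis = np.array(["HUMAN_OBSERVATION"] * n, dtype=object)
    violation = np.array([""] * n, dtype=object)

    n_viol = int(round(violation_fraction * n))
    viol_idx = rng.choice(n, size=n_viol, replace=False) if n_viol else np.array([], int)
    for k, idx in enumerate(viol_idx):
        kind = VIOLATION_TYPES[k % len(VIOLATION_TYPES)]
        violation[idx] = kind
        if kind == "fossil":
            basis[idx] = "FOSSIL_SPECIMEN"
        elif kind == "unknown_basis":
            basis[idx] = "UNKNOWN"
        elif kind == "high_uncertainty":
            unc[idx] = rng.uniform(1000, 5000)
        elif kind == "low_precision":
            unc[idx] = np.nan
            decimals[idx] = 1
        elif kind == "out_of_period":
            dates[idx] = f"{y0 - rng.integers(1, 10):04d}-06-15"

    return pd.DataFrame(
        {
            "species": species,
            "lon": lon,
            "lat": lat,
            "date": dates,
            "coord_uncertainty_m": unc,
            "basis_of_record": basis,
            "coord_decimals": decimals,
            "injected_violation": violation,
        }
    )


# ---------------------------------------------------------------------------
# trait pseudo-posteriors


def generate_trait_posteriors(
    true_params: dict,
    n_draws: int = 5000,
    dispersion: float = 0.02,
    seed: int = 0,
) -> TraitPosterior:
    """Pseudo-posterior draws around known true trait parameters.

    Thermal zeros (T0, Tm) receive additive normal jitter with SD
    ``dispersion * 10`` degC; positive scales (c, q) receive relative normal
    jitter with SD ``dispersion * true``.  Draws violating validity (T0 >= Tm
    or scale <= 0) are redrawn.  ``dispersion = 0`` collapses every draw to
    the true values.  This emulates consuming published trait posteriors; the
    shipped defaults are synthetic, not literature values.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    sd_t = dispersion * 10.0
    draws: dict[str, list] = {}
    for trait, p in true_params.items():
        out = []
        for _ in range(n_draws):
            for _attempt in range(100):
                t0 = rng.normal(p.T0, sd_t) if sd_t else p.T0
                tm = rng.normal(p.Tm, sd_t) if sd_t else p.Tm
                if isinstance(p, BriereParams):
                    c = rng.normal(p.c, dispersion * p.c) if dispersion else p.c
                    if t0 < tm and c > 0:
                        out.append(BriereParams(c, t0, tm))
                        break
                else:
                    q = rng.normal(p.q, dispersion * p.q) if dispersion else p.q
                    if t0 < tm and q > 0:
                        out.append(QuadraticParams(q, t0, tm, p.orientation))
                        break
            else:
                raise RuntimeError(f"could not draw valid parameters for trait {trait!r}")
        draws[trait] = out
    return TraitPosterior(draws)


def default_trait_truth(tmin: float = 12.0, tmax: float = 36.0) -> dict:
    """Synthetic true trait parameters whose M(T) support is (tmin, tmax).

    All numerator traits share the thermal zeros, so the composed abundance
    curve turns positive at ``tmin`` and vanishes at ``tmax`` exactly.
    Mortality's concave-up roots sit above the observed range so mu stays
    strictly positive (the floor clamp is inactive) across the grid.  These
    are illustrative synthetic values, not literature posteriors.
    """
    return {
        "EFD": QuadraticParams(q=0.04, T0=tmin, Tm=tmax, orientation="concave_down"),
        "pEA": QuadraticParams(q=0.006, T0=tmin, Tm=tmax, orientation="concave_down"),
        "MDR": BriereParams(c=7e-5, T0=tmin, Tm=tmax),
        "mu": QuadraticParams(q=1e-4, T0=tmax + 14.0, Tm=tmax + 54.0, orientation="concave_up"),
    }


def trait_posterior_to_csv(posterior: TraitPosterior, path) -> None:
    """Write draws as long-format CSV ``trait,draw,param,value``."""
    rows = []
    for trait, plist in posterior.draws.items():
        for d, p in enumerate(plist):
            if isinstance(p, BriereParams):
                items = [("c", p.c), ("T0", p.T0), ("Tm", p.Tm)]
            else:
                items = [("q", p.q), ("T0", p.T0), ("Tm", p.Tm), ("orientation", p.orientation)]
            rows.extend({"trait": trait, "draw": d, "param": k, "value": v} for k, v in items)
    pd.DataFrame(rows).to_csv(path, index=False)


def trait_posterior_from_csv(path) -> TraitPosterior:
    df = pd.read_csv(path)
    draws: dict[str, list] = {}
    for trait, tdf in df.groupby("trait"):
        plist = []
        for _, ddf in tdf.groupby("draw"):
            kv = dict(zip(ddf["param"], ddf["value"]))
            if "c" in kv:
                plist.append(BriereParams(float(kv["c"]), float(kv["T0"]), float(kv["Tm"])))
            else:
                plist.append(
                    QuadraticParams(
                        float(kv["q"]), float(kv["T0"]), float(kv["Tm"]), str(kv.get("orientation", "concave_down"))
                    )
                )
        draws[trait] = plist
    return TraitPosterior(draws)
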