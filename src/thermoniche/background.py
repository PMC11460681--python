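"""Ecoregion-constrained, bias-weighted pseudo-absence sampling.

Presence-only species distribution models need background (pseudo-absence)
points drawn from the species' *accessible area* — the region it could
plausibly have been recorded in — and with the same spatial sampling bias as
the occurrences, so the model learns environmental signal rather than
collection effort.  The accessible area is the set of ecoregions intersected
by the occurrence centroids buffered to 200 km (an upper bound on
wind-assisted mosquito mobility), plus all ecoregions adjacent to those.
Background cells are then drawn without replacement, weighted by the
sampling-effort bias mask restricted to the accessible area, at twice the
number of unique occurrence centroids, excluding the occurrence cells
themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.affinity import scale as shapely_scale
from shapely.geometry import Point

from .filtering import CellCentroidSet
from .grid import KM_PER_DEG_LAT, KM_PER_DEG_LON_EQ, RasterGrid
from .synthetic import BiasMask, Ecoregions

DEFAULT_BUFFER_KM = 200.0
BACKGROUND_RATIO = 2


@dataclass
class AccessibleArea:
    """Selected ecoregions and the land cells they contain."""

    ecoregion_ids: set[int]
    eligible: np.ndarray  # boolean (n_rows, n_cols): land cells in selected ecoregions
    grid: RasterGrid

    @property
    def n_eligible(self) -> int:
        return int(self.eligible.sum())


def _buffer_degrees(lon: float, lat: float, radius_km: float):
    """Ellipse approximating a km-radius circle at this latitude.

    Equirectangular: 1 deg lat ~ 110.57 km; 1 deg lon ~ 111.32*cos(lat) km.
    """
    dlat = radius_km / KM_PER_DEG_LAT
    dlon = radius_km / (KM_PER_DEG_LON_EQ * np.cos(np.deg2rad(lat)))
    return shapely_scale(Point(lon, lat).buffer(1.0, quad_segs=32), xfact=dlon, yfact=dlat)


def accessible_area(
    centroids: CellCentroidSet,
    ecoregions: Ecoregions,
    land: np.ndarray,
    buffer_km: float = DEFAULT_BUFFER_KM,
) -> AccessibleArea:
    """Ecoregions intersecting 200-km-buffered occurrence centroids, plus neighbors."""
    if len(centroids) == 0:
        raise ValueError("no occurrence centroids supplied")
    selected: set[int] = set()
    for lon, lat in centroids.table[["lon", "lat"]].itertuples(index=False):
        buf = _buffer_degrees(lon, lat, buffer_km)
        for eid, poly in ecoregions.polygons.items():
            if eid not in selected and poly.intersects(buf):
                selected.add(eid)
    if not selected:
        raise ValueError("no occurrence centroid intersects any ecoregion")
    with_adjacent = set(selected)
    for eid in selected:
        with_adjacent |= ecoregions.adjacency.get(eid, set())
    eligible = np.isin(ecoregions.labels, sorted(with_adjacent)) & land
    return AccessibleArea(with_adjacent, eligible, centroids.grid)


def build_bias_mask(effort_tallies: np.ndarray, area: AccessibleArea) -> BiasMask:
    """Sampling weights proportional to effort tallies within the area.

    Tallies are restricted to eligible cells and renormalized; if every
    eligible cell has zero tally the fallback is uniform weights over the
    area.
    """
    tallies = np.asarray(effort_tallies, dtype=float)
    if np.any(tallies < 0):
        raise ValueError("effort tallies must be nonnegative")
    w = np.where(area.eligible, tallies, 0.0)
    total = w.sum()
    if total <= 0:
        w = area.eligible.astype(float)
        total = w.sum()
    return BiasMask(w / total)


def _weighted_sample_without_replacement(rng, weights: np.ndarray, n: int) -> np.ndarray:
    """Indices of n cells drawn sequentially with p ~ remaining weights.

    Uses exponential sort keys (Efraimidis-Spirakis), distributionally
    equivalent to sequential draw-and-renormalize.
    """
    pos = np.flatnonzero(weights > 0)
    keys = rng.exponential(size=pos.size) / weights[pos]
    order = np.argsort(keys)
    return pos[order[:n]]


def sample_background(
    area: AccessibleArea,
    bias: BiasMask,
    occurrence_centroids: CellCentroidSet,
    seed,
    ratio: int = BACKGROUND_RATIO,
) -> CellCentroidSet:
    """Draw ratio x (number of occurrence centroids) background cells.

    Cells are distinct, drawn without replacement with probability
    proportional to the bias weights, restricted to the accessible area, and
    never coincide with occurrence cells.
    """
    grid = area.grid
    n_target = ratio * len(occurrence_centroids)
    w = np.where(area.eligible, bias.weights, 0.0).ravel()
    occ_ids = occurrence_centroids.cell_ids
    w[occ_ids] = 0.0
    n_avail = int((w > 0).sum())
    if n_avail < n_target:
        raise ValueError(
            f"insufficient eligible background cells: need {n_target}, "
            f"have {n_avail} (deficit {n_target - n_avail})"
        )
    rng = np.random.default_rng(seed)
    chosen = np.sort(_weighted_sample_without_replacement(rng, w, n_target))
    i, j = grid.id_to_index(chosen)
    lon, lat = grid.centroid(i, j)
    table = pd.DataFrame({"cell_id": chosen, "lon": lon, "lat": lat, "label": 0})
    return CellCentroidSet(table, grid)


@dataclass
class BreadthReport:
    passed: bool
    messages: list[str]
    occ_range: tuple[float, float]
    bg_range: tuple[float, float]


def thermal_breadth_check(occurrence_temps, background_temps) -> BreadthReport:
    """Check the background spans at least the occurrences' temperature range.

    Advisory only (pass/warn): a narrow background cannot inform thermal
    limits beyond the occupied range, which is exactly the failure mode that
    hides thermal maxima.
    """
    occ = np.asarray(occurrence_temps, dtype=float)
    bg = np.asarray(background_temps, dtype=float)
    if occ.size == 0 or bg.size == 0:
        raise ValueError("both temperature samples must be nonempty")
    messages = []
    if bg.min() > occ.min():
        messages.append(
            f"background lower tail ({bg.min():.2f} C) does not reach occurrences ({occ.min():.2f} C)"
        )
    if bg.max() < occ.max():
        messages.append(
            f"background upper tail ({bg.max():.2f} C) does not reach occurrences ({occ.max():.2f} C)"
        )
    return BreadthReport(
        passed=not messages,
        messages=messages,
        occ_range=(float(occ.min()), float(occ.max())),
        bg_range=(float(bg.min()), float(bg.max())),
    )
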