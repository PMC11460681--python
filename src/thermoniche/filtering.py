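"""Occurrence record cleaning cascade and spatial thinning to cell centroids.

Presence-only records arrive with heterogeneous quality: unknown or fossil
basis-of-record, coordinate uncertainty exceeding the grid cell, coordinates
reported to too few decimals, points in the ocean, or locations with missing
covariates or a zero-length activity season.  ``filter_records`` applies the
cleaning cascade in a fixed order and tallies each rule's rejections; the
surviving set is order-invariant regardless.  ``thin_to_centroids`` then
collapses records to the centroids of the unique occupied grid cells, which
spatially thins the data and damps uneven collection effort.

Rule order (each rule sees only records surviving the previous ones):

1. ``malformed`` — unparseable coordinates or missing required fields;
2. ``out_of_period`` — event date outside the study period;
3. ``basis_of_record`` — fossil or unknown basis;
4. ``coordinate_uncertainty`` — stated uncertainty >= 1000 m, or missing
   uncertainty with fewer than two decimal places in either coordinate;
5. ``not_on_land`` — cell is ocean (or outside the grid extent);
6. ``missing_covariate`` — any covariate NaN at the cell;
7. ``no_activity_season`` — season length 0 at the cell (skipped for
   year-round species).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import RasterGrid

MAX_UNCERTAINTY_M = 1000.0
MIN_COORD_DECIMALS = 2

RULE_ORDER = (
    "malformed",
    "out_of_period",
    "basis_of_record",
    "coordinate_uncertainty",
    "not_on_land",
    "missing_covariate",
    "no_activity_season",
)

_BAD_BASIS = {"FOSSIL_SPECIMEN", "FOSSIL", "UNKNOWN", ""}


@dataclass
class FilterResult:
    survivors: pd.DataFrame
    tally: dict[str, int]  # per-rule rejection counts, in application order

    @property
    def n_input(self) -> int:
        return len(self.survivors) + sum(self.tally.values())


def filter_records(
    records: pd.DataFrame,
    covariates: dict[str, RasterGrid],
    land: np.ndarray,
    season_length: np.ndarray | None = None,
    study_period: tuple[int, int] = (2000, 2019),
) -> FilterResult:
    """Apply the cleaning cascade; return survivors plus per-rule tally.

    ``season_length`` is a per-cell array (None for year-round species).
    Covariate grids must share one grid convention; the first grid supplies
    the cell geometry.
    """
    if len(records) == 0:
        raise ValueError("no occurrence records supplied")
    template = next(iter(covariates.values()))
    df = records.copy().reset_index(drop=True)
    tally = {rule: 0 for rule in RULE_ORDER}

    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    malformed = (
        lon.isna()
        | lat.isna()
        | (lat.abs() > 90)
        | (lon.abs() > 180)
        | df["species"].isna()
    )
    tally["malformed"] = int(malformed.sum())
    df, lon, lat = df[~malformed], lon[~malformed], lat[~malformed]

    years = pd.to_datetime(df["date"], errors="coerce").dt.year
    in_period = years.notna() & (years >= study_period[0]) & (years <= study_period[1])
    tally["out_of_period"] = int((~in_period).sum())
    df, lon, lat = df[in_period], lon[in_period], lat[in_period]

    basis = df["basis_of_record"].fillna("UNKNOWN").str.upper()
    ok_basis = ~basis.isin(_BAD_BASIS)
    tally["basis_of_record"] = int((~ok_basis).sum())
    df, lon, lat = df[ok_basis], lon[ok_basis], lat[ok_basis]

    unc = pd.to_numeric(df["coord_uncertainty_m"], errors="coerce")
    decimals = pd.to_numeric(df["coord_decimals"], errors="coerce").fillna(0)
    ok_unc = (unc < MAX_UNCERTAINTY_M) | (unc.isna() & (decimals >= MIN_COORD_DECIMALS))
    tally["coordinate_uncertainty"] = int((~ok_unc).sum())
    df, lon, lat = df[ok_unc], lon[ok_unc], lat[ok_unc]

    in_extent = template.contains(lon.to_numpy(), lat.to_numpy())
    on_land = in_extent.copy()
    if in_extent.any():
        i, j = template.cell_index(lon.to_numpy()[in_extent], lat.to_numpy()[in_extent])
        on_land[in_extent] = land[i, j]
    tally["not_on_land"] = int((~on_land).sum())
    df, lon, lat = df[on_land], lon[on_land], lat[on_land]

    i, j = template.cell_index(lon.to_numpy(), lat.to_numpy())
    has_all = np.ones(len(df), dtype=bool)
    for g in covariates.values():
        has_all &= ~np.isnan(g.values[i, j])
    tally["missing_covariate"] = int((~has_all).sum())
    df, i, j = df[has_all], i[has_all], j[has_all]

    if season_length is not None:
        in_season = np.asarray(season_length)[i, j] > 0
        tally["no_activity_season"] = int((~in_season).sum())
        df = df[in_season]

    return FilterResult(df.reset_index(drop=True), tally)


@dataclass
class CellCentroidSet:
    """Unique occupied cells: centroid coordinates, label, covariate values."""

    table: pd.DataFrame  # columns: cell_id, lon, lat, label [, covariates...]
    grid: RasterGrid

    def __len__(self) -> int:
        return len(self.table)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.table["cell_id"].to_numpy()


def thin_to_centroids(records: pd.DataFrame, grid: RasterGrid, label: int = 1) -> CellCentroidSet:
    """Collapse filtered records to unique cell centroids (idempotent)."""
    df = records.drop_duplicates(subset=["lon", "lat"])
    i, j = grid.cell_index(df["lon"].to_numpy(), df["lat"].to_numpy())
    ids = np.unique(grid.cell_id(i, j))
    ci, cj = grid.id_to_index(ids)
    lon, lat = grid.centroid(ci, cj)
    table = pd.DataFrame({"cell_id": ids, "lon": lon, "lat": lat, "label": label})
    return CellCentroidSet(table, grid)


def attach_covariates(centroids: CellCentroidSet, covariates: dict[str, RasterGrid]) -> tuple[CellCentroidSet, int]:
    """Attach one value per covariate at each centroid's cell.

    Centroids with any missing covariate are dropped; returns the enriched
    set and the dropped count.  A centroid outside the grid extent raises.
    """
    table = centroids.table.copy()
    lon = table["lon"].to_numpy()
    lat = table["lat"].to_numpy()
    outside = ~next(iter(covariates.values())).contains(lon, lat)
    if outside.any():
        k = int(np.argmax(outside))
        raise ValueError(f"centroid (lon={lon[k]}, lat={lat[k]}) lies outside the covariate extent")
    i, j = next(iter(covariates.values())).cell_index(lon, lat)
    for name, g in covariates.items():
        table[name] = g.values[i, j]
    keep = ~table[list(covariates)].isna().any(axis=1)
    dropped = int((~keep).sum())
    return CellCentroidSet(table[keep].reset_index(drop=True), centroids.grid), dropped
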