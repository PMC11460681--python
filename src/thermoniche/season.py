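"""Activity-season masks and in-season temperature statistics.

Temperate mosquitoes enter photoperiodic diapause when daylight is short;
Sahelian species aestivate through the dry season.  To compare field thermal
responses with laboratory measurements taken on active mosquitoes,
temperature covariates are computed only over each species' activity season:

* ``year_round`` — no mask; annual mean/SD.
* ``photoperiod`` — days with at least 9 hours of daylight.
* ``precipitation`` — days whose trailing 30-day precipitation total is at
  least 50 mm (the climatological wet season).

A 365-day no-leap calendar is used throughout and the trailing precipitation
window wraps across the year boundary: the inputs are climatological average
years, which are cyclic by construction.

Day length follows the CBM model of Forsythe et al. (1995) with daylight
defined sunrise-to-sunset at solar center on the horizon (daylight
coefficient p = 0); the coefficient is exposed for twilight-inclusive
variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_DAYS = 365
PHOTOPERIOD_HOURS = 9.0
PRECIP_MM = 50.0
PRECIP_WINDOW_DAYS = 30

ACTIVITY_MODES = ("year_round", "photoperiod", "precipitation")


def day_length(latitude, day_of_year, daylight_coefficient: float = 0.0):
    """Hours of daylight (CBM model).

    ``latitude`` in degrees (|lat| <= 90), ``day_of_year`` in 1..365.  Both
    broadcast.  Polar day/night saturate at 24/0 h.
    """
    lat = np.asarray(latitude, dtype=float)
    doy = np.asarray(day_of_year, dtype=float)
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitude must satisfy |lat| <= 90")
    doy = (doy - 1) % N_DAYS + 1  # day-of-year is cyclic; fractions allowed
    theta = 0.2163108 + 2 * np.arctan(0.9671396 * np.tan(0.00860 * (doy - 186)))
    phi = np.arcsin(0.39795 * np.cos(theta))  # solar declination, radians
    p_rad = np.deg2rad(daylight_coefficient)
    lat_rad = np.deg2rad(lat)
    cos_arg = (np.sin(p_rad) + np.sin(lat_rad) * np.sin(phi)) / (
        np.cos(lat_rad) * np.cos(phi)
    )
    cos_arg = np.clip(cos_arg, -1.0, 1.0)
    hours = 24 - (24 / np.pi) * np.arccos(cos_arg)
    return hours if hours.ndim else float(hours)


@dataclass
class SeasonMask:
    """Per-cell day-of-year activity flags (365-day convention)."""

    active: np.ndarray  # boolean, shape (..., 365)

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=bool)
        if self.active.shape[-1] != N_DAYS:
            raise ValueError(f"last axis must have length {N_DAYS}")

    @property
    def season_length(self) -> np.ndarray:
        """Number of active days per cell."""
        return self.active.sum(axis=-1)


def photoperiod_season_mask(latitude, threshold_hours: float = PHOTOPERIOD_HOURS) -> SeasonMask:
    """Days with day length >= ``threshold_hours`` (boundary inclusive).

    ``latitude`` may be any shape; the result gains a trailing 365 axis.
    """
    lat = np.asarray(latitude, dtype=float)
    doy = np.arange(1, N_DAYS + 1)
    hours = day_length(lat[..., None], doy[(None,) * lat.ndim])
    return SeasonMask(np.asarray(hours) >= threshold_hours)


def precipitation_season_mask(
    daily_precip,
    threshold_mm: float = PRECIP_MM,
    window_days: int = PRECIP_WINDOW_DAYS,
) -> SeasonMask:
    """Days whose trailing ``window_days`` precipitation sum >= ``threshold_mm``.

    ``daily_precip`` has shape (..., 365) in mm/day; the window covers days
    d-window+1..d and wraps the (cyclic climatological) year boundary.
    """
    pr = np.asarray(daily_precip, dtype=float)
    if pr.shape[-1] != N_DAYS:
        raise ValueError(f"daily precipitation needs a trailing {N_DAYS}-day axis")
    if np.any(pr < 0):
        raise ValueError("precipitation cannot be negative")
    wrapped = np.concatenate([pr[..., -(window_days - 1):], pr], axis=-1)
    csum = np.cumsum(wrapped, axis=-1)
    zero = np.zeros(wrapped.shape[:-1] + (1,))
    csum = np.concatenate([zero, csum], axis=-1)
    trailing = csum[..., window_days:] - csum[..., :-window_days]
    # float tolerance so an exact-threshold sum (e.g. 30 * 50/30) counts as active
    return SeasonMask(trailing >= threshold_mm - 1e-9)


def year_round_mask(shape=()) -> SeasonMask:
    """All-days-active mask (species without seasonal dormancy)."""
    return SeasonMask(np.ones(tuple(shape) + (N_DAYS,), dtype=bool))


@dataclass
class SeasonalTemperatureSummary:
    """In-season temperature mean/SD per cell; NaN where season length is 0."""

    mean: np.ndarray
    sd: np.ndarray
    season_length: np.ndarray


def season_temperature_stats(daily_temperature, mask: SeasonMask, ddof: int = 0) -> SeasonalTemperatureSummary:
    """Mean and (population, ddof=0) SD of temperature over active days.

    ``daily_temperature`` has shape (..., 365) aligned to day-of-year.  Cells
    with zero-length seasons get NaN statistics.
    """
    temp = np.asarray(daily_temperature, dtype=float)
    if temp.shape != mask.active.shape:
        raise ValueError("temperature series and mask shapes differ")
    length = mask.season_length
    n = np.maximum(length, 1)  # avoid 0-division; zero-length cells NaN'd below
    total = np.where(mask.active, temp, 0.0).sum(axis=-1)
    total_sq = np.where(mask.active, temp**2, 0.0).sum(axis=-1)
    mean = total / n
    denom = np.maximum(n - ddof, 1)
    var = np.maximum(total_sq - n * mean**2, 0.0) / denom
    sd = np.sqrt(var)
    mean = np.where(length > 0, mean, np.nan)
    sd = np.where(length > ddof, sd, np.nan)
    return SeasonalTemperatureSummary(mean, sd, length)
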