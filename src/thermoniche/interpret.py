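"""Model interpretation: partial dependence, gain importance, thermal extrema.

The fitted classifier is interrogated rather than trusted as a black box:

* the univariate partial dependence of occurrence probability on temperature
  — pdp(t) is the mean predicted probability over every observed covariate
  combination with temperature forced to t;
* gain-based variable importance, summarized across bootstrap iterations;
* field thermal limits read off the PDP by empirical (forward-difference)
  derivative rules: the thermal minimum is the first temperature whose
  derivative is positive and stays positive for the next step too
  (``persistent_rise``), or alternatively the temperature with the largest
  derivative (``steepest``); the thermal optimum is the curve's discrete
  maximum, flagged absent when attained at the final grid point.  Thermal
  maxima are deliberately never extracted: occurrence PDPs plateau rather
  than decline within the observed temperature range, so a maxima rule would
  manufacture structure the data cannot support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .sdm import FitResult, FittedModelBundle

DEFAULT_PDP_POINTS = 100

EXTRACTION_MODES = ("persistent_rise", "steepest")


@dataclass
class PartialDependenceCurve:
    feature: str
    grid: np.ndarray  # ascending feature values
    values: np.ndarray  # mean predicted probability per grid point
    scaled: np.ndarray = field(init=False)  # min-max scaled to [0, 1]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.size > 1 and not np.all(np.diff(self.grid) > 0):
            raise ValueError("PDP grid must be strictly ascending")
        span = self.values.max() - self.values.min()
        if span > 0:
            self.scaled = (self.values - self.values.min()) / span
        else:
            warnings.warn("constant partial dependence curve; scaled values set to 0")
            self.scaled = np.zeros_like(self.values)


def default_grid(table: pd.DataFrame, feature: str, n_points: int = DEFAULT_PDP_POINTS) -> np.ndarray:
    """Evenly spaced grid spanning the pooled occurrence+background range."""
    lo = float(table[feature].min())
    hi = float(table[feature].max())
    return np.linspace(lo, hi, n_points)


def compute_pdp(fit: FitResult, table: pd.DataFrame, feature: str, grid=None) -> PartialDependenceCurve:
    """pdp(t) = mean over rows of the prediction with ``feature`` forced to t."""
    if feature not in table.columns:
        raise ValueError(f"feature {feature!r} not in table")
    grid = default_grid(table, feature) if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty PDP grid")
    feats = fit.feature_names
    X = table[feats].to_numpy(dtype=float)
    col = feats.index(feature)
    n = X.shape[0]
    # one matrix with the rows tiled per grid point; forced column varies by block
    tiled = np.tile(X, (grid.size, 1))
    tiled[:, col] = np.repeat(grid, n)
    preds = fit.booster.predict(xgb.DMatrix(tiled, feature_names=feats)).astype(np.float64)
    values = preds.reshape(grid.size, n).mean(axis=1)
    return PartialDependenceCurve(feature, grid, values)


@dataclass
class VariableImportanceTable:
    per_iteration: pd.DataFrame  # rows = iterations, columns = features (gain share)
    summary: pd.DataFrame  # index = features; columns = median, min, max

    def ranking(self) -> list[str]:
        return list(self.summary.sort_values("median", ascending=False).index)


def variable_importance(bundle: FittedModelBundle) -> VariableImportanceTable:
    """Per-iteration gain shares (total gain, normalized per model) + summary.

    Features never split upon carry gain 0.
    """
    feats = bundle.iterations[0].fit.feature_names
    rows = []
    for it in bundle.iterations:
        raw = it.fit.booster.get_score(importance_type="total_gain")
        gains = np.array([raw.get(f, 0.0) for f in feats])
        total = gains.sum()
        rows.append(gains / total if total > 0 else gains)
    per_it = pd.DataFrame(rows, columns=feats)
    summary = pd.DataFrame(
        {"median": per_it.median(), "min": per_it.min(), "max": per_it.max()}
    )
    return VariableImportanceTable(per_it, summary)


# ---------------------------------------------------------------------------
# thermal extrema from PDPs


def _forward_differences(curve: PartialDependenceCurve) -> np.ndarray:
    return np.diff(curve.values) / np.diff(curve.grid)


def extract_thermal_minimum(curve: PartialDependenceCurve, mode: str = "persistent_rise"):
    """Field thermal minimum from the PDP's empirical derivative, or None.

    ``persistent_rise``: the first grid temperature t_i with d_i > 0 and
    d_{i+1} > 0 (strict — flat segments never trigger).  ``steepest``: the
    grid temperature with the largest positive derivative (lowest
    temperature on ties).
    """
    if mode not in EXTRACTION_MODES:
        raise ValueError(f"mode must be one of {EXTRACTION_MODES}")
    if curve.grid.size < 3:
        raise ValueError("need at least 3 grid points")
    d = _forward_differences(curve)
    if mode == "persistent_rise":
        qualifying = np.flatnonzero((d[:-1] > 0) & (d[1:] > 0))
        if qualifying.size == 0:
            return None
        return float(curve.grid[qualifying[0]])
    if np.max(d) <= 0:
        return None
    return float(curve.grid[int(np.argmax(d))])  # argmax takes first (lowest T) on ties


def extract_thermal_optimum(curve: PartialDependenceCurve):
    """Grid temperature of the PDP maximum (lowest T on ties), or None.

    Absent ("no interior optimum") when the maximum sits at the final grid
    point — a curve still rising at the hot edge has no detected optimum —
    or when the curve is exactly constant.
    """
    if curve.grid.size < 3:
        raise ValueError("need at least 3 grid points")
    v = curve.values
    if np.all(v == v[0]):
        return None
    k = int(np.argmax(v))
    if k == v.size - 1:
        return None
    return float(curve.grid[k])


@dataclass
class ThermalExtremaEstimate:
    """Across-iteration summary of one extracted quantity."""

    median: float
    minimum: float
    maximum: float
    n_defined: int
    n_undefined: int
    mode: str


def summarize_extrema(values: list, mode: str = "persistent_rise") -> ThermalExtremaEstimate | None:
    """Median and full min-max range across iterations where defined.

    Returns None (summary absent) when every iteration is undefined.
    """
    if len(values) == 0:
        raise ValueError("need at least one iteration")
    defined = [v for v in values if v is not None]
    if not defined:
        return None
    arr = np.asarray(defined, dtype=float)
    return ThermalExtremaEstimate(
        median=float(np.median(arr)),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        n_defined=len(defined),
        n_undefined=len(values) - len(defined),
        mode=mode,
    )


@dataclass
class FieldExtrema:
    """Per-iteration PDP curves and the summarized field Tmin/Topt."""

    curves: list[PartialDependenceCurve]
    tmin: ThermalExtremaEstimate | None
    tmin_steepest: ThermalExtremaEstimate | None
    topt: ThermalExtremaEstimate | None


def field_thermal_extrema(
    bundle: FittedModelBundle,
    feature: str = "temperature_mean",
    grid=None,
    n_points: int = DEFAULT_PDP_POINTS,
) -> FieldExtrema:
    """PDP per bootstrap iteration, extrema per curve, summaries across them."""
    grid = default_grid(bundle.table, feature, n_points) if grid is None else grid
    curves = [compute_pdp(it.fit, bundle.table, feature, grid) for it in bundle.iterations]
    tmins = [extract_thermal_minimum(c, "persistent_rise") for c in curves]
    tmins_s = [extract_thermal_minimum(c, "steepest") for c in curves]
    topts = [extract_thermal_optimum(c) for c in curves]
    return FieldExtrema(
        curves=curves,
        tmin=summarize_extrema(tmins, "persistent_rise"),
        tmin_steepest=summarize_extrema(tmins_s, "steepest"),
        topt=summarize_extrema(topts, "argmax"),
    )
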