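"""Laboratory-derived thermal performance curves and mechanistic abundance.

Mosquito life-history traits respond unimodally to temperature.  Following
the trait literature, asymmetric responses such as mosquito development rate
(MDR) are modeled with a Briere function,

    f(T) = c * T * (T - T0) * sqrt(Tm - T)   on (T0, Tm), else 0,

while symmetric responses use quadratics: concave-down for eggs per female
per day (EFD) and egg-to-adult survival (pEA),

    f(T) = q * (T - T0) * (Tm - T)   truncated below at 0,

and concave-up for adult mortality rate (mu),

    f(T) = q * (T - T0) * (T - Tm),

which is large at thermal extremes and smallest near the midpoint of its
roots.  Equilibrium mosquito abundance as a function of temperature is the
trait composition

    M(T) = EFD(T) * pEA(T) * MDR(T) / mu(T)^2,

zero wherever any numerator trait is non-positive, with mu clamped below at a
small positive floor so the division stays finite where the concave-up
quadratic approaches or crosses zero.

Uncertainty is propagated by evaluating M(T) for each joint posterior draw of
the trait parameters (draw i of every trait combined), then summarizing the
per-draw thermal minimum (first temperature with M > 0), optimum (argmax) and
maximum (last temperature with M > 0) by their median and 2.5th/97.5th
percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_GRID = np.round(np.arange(0.0, 45.0 + 1e-9, 0.1), 10)
DEFAULT_MU_FLOOR = 1e-3  # day^-1

NUMERATOR_TRAITS = ("EFD", "pEA", "MDR")


@dataclass(frozen=True)
class BriereParams:
    """Briere-1 parameters: positive scale ``c`` and thermal zeros T0 < Tm."""

    c: float
    T0: float
    Tm: float

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError("Briere scale c must be positive")
        if not self.T0 < self.Tm:
            raise ValueError("Briere requires T0 < Tm")


@dataclass(frozen=True)
class QuadraticParams:
    """Symmetric quadratic with positive scale ``q``, roots T0 < Tm."""

    q: float
    T0: float
    Tm: float
    orientation: str = "concave_down"

    def __post_init__(self) -> None:
        if not self.q > 0:
            raise ValueError("quadratic scale q must be positive")
        if not self.T0 < self.Tm:
            raise ValueError("quadratic requires T0 < Tm")
        if self.orientation not in ("concave_down", "concave_up"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


def briere(T, p: BriereParams):
    """Briere-1 trait value; 0 outside (T0, Tm), positive inside."""
    T = np.asarray(T, dtype=float)
    inside = (T > p.T0) & (T < p.Tm)
    out = np.zeros_like(T)
    Ti = T[inside]
    out[inside] = p.c * Ti * (Ti - p.T0) * np.sqrt(p.Tm - Ti)
    return out if out.ndim else float(out)


def quadratic(T, p: QuadraticParams):
    """Symmetric quadratic trait value.

    concave_down: 0 at the roots, maximal at their midpoint, truncated at 0
    outside.  concave_up: the raw parabola q*(T-T0)*(T-Tm) — minimum at the
    midpoint, growing toward both ends (callers clamp as appropriate).
    """
    T = np.asarray(T, dtype=float)
    if p.orientation == "concave_down":
        out = np.maximum(p.q * (T - p.T0) * (p.Tm - T), 0.0)
    else:
        out = p.q * (T - p.T0) * (T - p.Tm)
    return out if out.ndim else float(out)


def eval_trait(T, params):
    if isinstance(params, BriereParams):
        return briere(T, params)
    if isinstance(params, QuadraticParams):
        return quadratic(T, params)
    raise TypeError(f"unsupported trait parameter type {type(params)!r}")


@dataclass
class TraitPosterior:
    """Per-trait posterior parameter draws (equal draw count across traits).

    ``draws[trait]`` is a list of parameter sets; draw i of every trait is
    combined when composing M(T).
    """

    draws: dict[str, list]

    def __post_init__(self) -> None:
        required = set(NUMERATOR_TRAITS) | {"mu"}
        if set(self.draws) != required:
            raise ValueError(f"traits must be exactly {sorted(required)}")
        counts = {t: len(d) for t, d in self.draws.items()}
        if len(set(counts.values())) != 1:
            raise ValueError(f"unequal draw counts across traits: {counts}")
        if self.n_draws < 1:
            raise ValueError("need at least one draw")

    @property
    def n_draws(self) -> int:
        return len(next(iter(self.draws.values())))

    @classmethod
    def from_point(cls, params: dict, n_draws: int = 1) -> "TraitPosterior":
        """Replicate a single parameter set per trait into n identical draws."""
        return cls({t: [p] * n_draws for t, p in params.items()})


@dataclass
class AbundanceCurve:
    """Per-draw M(T) over a temperature grid plus pointwise summaries."""

    grid: np.ndarray  # ascending temperatures, degC
    values: np.ndarray  # (n_draws, n_grid)
    median: np.ndarray = field(init=False)
    lower: np.ndarray = field(init=False)  # 2.5th percentile
    upper: np.ndarray = field(init=False)  # 97.5th percentile

    def __post_init__(self) -> None:
        self.median = np.median(self.values, axis=0)
        self.lower = np.percentile(self.values, 2.5, axis=0)
        self.upper = np.percentile(self.values, 97.5, axis=0)


def abundance_curve(traits: TraitPosterior, grid=None, mu_floor: float = DEFAULT_MU_FLOOR) -> AbundanceCurve:
    """Compose per-draw M(T) = EFD*pEA*MDR/mu^2 over a temperature grid.

    M is set to 0 wherever any numerator trait is <= 0; mu is clamped below
    at ``mu_floor`` (> 0) before squaring.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("temperature grid is empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("temperature grid must be strictly ascending")
    if not mu_floor > 0:
        raise ValueError("mu_floor must be positive")

    n = traits.n_draws
    M = np.empty((n, grid.size))
    for i in range(n):
        efd = eval_trait(grid, traits.draws["EFD"][i])
        pea = eval_trait(grid, traits.draws["pEA"][i])
        mdr = eval_trait(grid, traits.draws["MDR"][i])
        mu = np.maximum(eval_trait(grid, traits.draws["mu"][i]), mu_floor)
        m = efd * pea * mdr / mu**2
        m[(efd <= 0) | (pea <= 0) | (mdr <= 0)] = 0.0
        M[i] = m
    return AbundanceCurve(grid, M)


def curve_extrema(values, grid):
    """(Tmin, Topt, Tmax) of one M(T) draw on a grid; all None if M == 0.

    Tmin: first grid temperature with M > 0.  Topt: grid argmax (lowest
    temperature on ties).  Tmax: last grid temperature with M > 0.
    """
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("temperature grid must be strictly ascending")
    pos = np.flatnonzero(values > 0)
    if pos.size == 0:
        return None, None, None
    tmin = float(grid[pos[0]])
    tmax = float(grid[pos[-1]])
    topt = float(grid[int(np.argmax(values))])  # argmax takes first on ties
    return tmin, topt, tmax


@dataclass
class MechanisticExtrema:
    """Median and 95% CI of per-draw thermal limits/optimum."""

    summary: dict  # {"Tmin"|"Topt"|"Tmax": {"median","lower","upper"}}
    n_draws: int
    n_undefined: int


def posterior_summary(curve: AbundanceCurve) -> MechanisticExtrema:
    """Summarize per-draw extrema by median and 2.5/97.5 percentiles."""
    per_draw = [curve_extrema(curve.values[i], curve.grid) for i in range(curve.values.shape[0])]
    defined = [e for e in per_draw if e[0] is not None]
    n_undef = len(per_draw) - len(defined)
    if not defined:
        raise ValueError("no posterior draw produced a positive abundance curve")
    arr = np.array(defined)  # (n_defined, 3)
    names = ("Tmin", "Topt", "Tmax")
    summary = {
        name: {
            "median": float(np.median(arr[:, k])),
            "lower": float(np.percentile(arr[:, k], 2.5)),
            "upper": float(np.percentile(arr[:, k], 97.5)),
        }
        for k, name in enumerate(names)
    }
    return MechanisticExtrema(summary, n_draws=len(per_draw), n_undefined=n_undef)
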