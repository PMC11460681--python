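# Methods

## The question and the two estimators

Mosquito life-history traits respond unimodally to temperature, and
laboratory experiments yield trait thermal performance curves with explicit
lower limits, optima and upper limits.  Whether those limits govern where
mosquitoes actually occur is an empirical question: field distributions are
shaped by sampling effort, accessible geography and covarying habitat
factors.  This package implements both estimators — a mechanistic
trait-composition model and a statistical occurrence model — on a common
synthetic test bed with known truth, so that the comparison machinery
itself can be validated by parameter recovery.

## Mechanistic abundance

Equilibrium abundance is `M(T) = EFD(T)·pEA(T)·MDR(T)/μ(T)²`.  Trait forms
are the standard ones from the trait-fitting literature: Briere-1
`cT(T−T0)√(Tm−T)` for development rate (zero outside `(T0, Tm)`),
concave-down quadratics `q(T−T0)(Tm−T)` truncated at zero for fecundity and
egg-to-adult survival, and a concave-up quadratic `q(T−T0)(T−Tm)` for adult
mortality.  M is set to zero wherever a numerator trait is non-positive,
and μ is clamped below at `mu_floor` (default 1e-3 day⁻¹, configurable) so
the division cannot blow up where the mortality parabola approaches zero;
whenever the clamp would bind inside the observed range the 1/μ² term, not
the traits, would set the optimum, so the shipped synthetic mortality
parameters place the parabola's roots above the grid and keep the clamp
inactive.

Uncertainty propagates by composing draw *i* of every trait (traits
independent across draws) on a fixed grid, default 0–45 °C at 0.1 °C —
finer than any tolerance used downstream.  Per draw, Tmin is the first grid
temperature with M > 0, Topt the grid argmax (lowest temperature on exact
ties), Tmax the last grid temperature with M > 0; summaries are medians and
2.5/97.5 percentiles over draws.  Trait parameter draws are emulated
pseudo-posteriors: normal jitter around true values (SD = `dispersion`×10 °C
for thermal zeros, `dispersion`×truth for scales), redrawn until valid
(`T0 < Tm`, positive scale).  The shipped trait values are synthetic
illustrations, not literature posteriors.

## Synthetic world

The generator emulates, at desk scale, the structure of a real
occurrence-modeling study:

* **Grid.** 0.05° cells (cell-size-agnostic logic) over a few-degree
  extent; half-open cell membership `[low, high)` on both axes resolves
  boundary points deterministically.  Distances use an equirectangular
  km approximation — adequate over these extents and keeping the 200-km
  buffer meaningful without geodesic machinery.
* **Temperature.** A south–north gradient spanning `(Tmin*−6, Tmax*+6)`
  plus smooth bounded noise (±0.8 °C), so the attained range strictly
  contains `(Tmin*−5, Tmax*+5)` and both extrema are identifiable.
  Seasonal temperature SD has only a mild latitudinal trend so the two
  temperature covariates pass the collinearity screen.
* **Auxiliary covariates.** Four smooth fields (vegetation index, dry-
  quarter precipitation, human population density, forest cover) built as
  `ρ·z_T + √(1−ρ²)·noise` with ρ ∈ {0.45, −0.35, 0.15, 0} plus white noise
  — correlated with temperature but below the |r| < 0.8 screening
  threshold by construction.  They carry no causal effect on occurrence.
* **Truth.** Occurrence suitability is a Briere curve
  `s(T) ∝ T(T−Tmin*)(Tmax*−T)^m` with the exponent solved in closed form so
  the peak sits exactly at Topt*: `m = (Tmax*−Topt*)(1/Topt* + 1/(Topt*−Tmin*))`.
* **Effort bias.** Weights `exp(c·g)` for a smooth hotspot field `g`,
  normalized over land; `c → 0` gives uniform effort, the default `c = 2`
  gives ~7× peak-to-trough effort.
* **Occurrences.** `n` records drawn with replacement with probability
  ∝ suitability × effort, jittered within their cell; 10% carry labeled
  filter-violating metadata (fossil/unknown basis, 1–5 km uncertainty,
  low coordinate precision, out-of-period dates) so the cleaning cascade
  has known expected survivors.
* **Ecoregions.** Voronoi cells of uniform random seeds, clipped to the
  extent; rook adjacency (shared boundary of positive length), since
  point-touch adjacency is degenerate for Voronoi tessellations.

What the generator does *not* emulate: taxonomy, real ecoregion geometry,
satellite product semantics, spatial autocorrelation of residual habitat
quality, or multi-year climate variability.  Passing recovery tests
therefore show the pipeline's statistical machinery is correct, not that
real-data results would share its error bars.

## Activity seasons

Day length follows the CBM model (Forsythe et al. 1995) with daylight
defined sunrise-to-sunset at solar center (daylight coefficient 0,
configurable for twilight variants).  The photoperiod season is days with
≥ 9 h daylight (boundary inclusive); the precipitation season is days whose
trailing 30-day total is ≥ 50 mm, on a cyclic 365-day climatological year
(the window wraps the year boundary).  In-season temperature statistics
pool all active days and use the population SD — the mask defines the full
population of in-season days — with `ddof` configurable.  Note the CBM
formula is hemispherically antisymmetric only to ~0.25 h at mid-latitudes
(orbital eccentricity), which bounds how exactly mirrored-latitude
properties can hold.

## Cleaning, thinning, background

The cleaning cascade applies, in a fixed order for reproducible tallies:
malformed rows; study-period dates; fossil/unknown basis; coordinate
uncertainty < 1000 m or (missing uncertainty and ≥ 2 reported decimals in
both coordinates — an explicit metadata field, because trailing zeros are
unrecoverable from floats); on-land; non-missing covariates; positive
activity-season length (skipped for year-round species).  The survivor set
is order-invariant; rejections plus survivors always equal the input count.
Survivors are thinned to unique cell centroids (idempotent).

The accessible area is the union of ecoregions intersecting any 200-km
buffered occurrence centroid, plus their rook neighbors.  Background
weights are the effort tallies restricted to the area and renormalized
(only relative weights matter; all-zero tallies fall back to uniform).
Exactly 2× the occurrence-centroid count of distinct background cells is
drawn without replacement via exponential sort keys — distributionally
equivalent to sequential draw-and-renormalize, which serves as the test
oracle — excluding occurrence cells, since one cell cannot be both presence
and pseudo-absence in the training table.  A thermal-breadth check warns
(never fails) when the background's temperature range does not cover the
occurrences'.

## Model fitting and interpretation

Training tables are screened for pairwise |r| ≥ 0.8 (advisory), split
80/20 with stratification, and fit with XGBoost binary classifiers
(`tree_method=hist`, single-thread for determinism).  Hyperparameters
(learning rate 1e-4–0.3 on a log axis, depth 2–50, min child weight 1–50,
row subsample 0.25–1, column subsample 0.5–1, min split loss 0–100) are
tuned by a Gaussian-process surrogate (Matern 5/2 on the unit cube) with
expected improvement, at most 24 evaluations; each proposal is scored by
mean out-of-fold log loss over 5 stratified folds, with the boosting-round
count (≤ 10,000) chosen by the fold-averaged minimum under early stopping
(patience 50).  The initial design anchors two standard configurations —
the backend defaults and the conventional conservative small-data profile
(learning rate 0.05, depth 4) — followed by a Latin hypercube; EI
candidates mix global uniform points with local perturbations of the
incumbent.  The argmin proposal is refit on the full training table and
evaluated by rank-statistic ROC/AUC on both sets.  The procedure repeats
over bootstrap splits (default 20; tuning is shared from the first split
unless `tune_per_iteration=True`).  Folds are stratified to avoid
single-class folds at desk scale.

Partial dependence forces the temperature column to each grid value
(default: 100 even points spanning the pooled occurrence+background range)
and averages predictions over all table rows in float64; it is tested for
exact (1e-10) agreement with a row-loop oracle.  Importance is per-model
total gain normalized to shares, summarized by median and min–max range
across iterations.  Extrema rules operate on forward differences: Tmin at
the first `d_i > 0 ∧ d_{i+1} > 0` (strict, so flat segments never trigger),
alternative Tmin at the largest positive difference, Topt at the discrete
argmax (lowest temperature on exact ties; absent when attained at the last
grid point or when the curve is constant).  No thermal maximum is ever
extracted: occurrence PDPs plateau rather than decline within observed
temperature ranges.

## Desk-scale problem sizes and what recovery shows

The default study profile uses 60×60-cell worlds, ~1,000 occurrence
centroids, ~2,000 background cells, 5 bootstrap fits, 8 tuning rounds and
≤ 300 boosting rounds; the four-species comparison uses the same profile
per species.  At this scale the lower thermal limit recovers tightly
(median error well under 1 °C across replicate worlds): it lives on the
steep flank of the response, where the signal is strong.  The optimum is
intrinsically noisier: with ~1,000 occupied cells among ~3,300, per-cell
occupancy saturates (occupied-probability ≈ 1−(1−p)^n with n·p ≈ 1), which
compresses the presence/background contrast to a few percent across a
~10 °C plateau around the optimum, and the argmax of a plateau is fragile —
individual worlds' PDP optima wander by ±4–5 °C even under deliberately
smooth, log-loss-optimal fits.  Medians across replicate worlds remain
accurate (the acceptance script reports both the per-world recovery count
and the across-world medians).  This saturation artifact shrinks with grid
size and is negligible at the scales real studies operate at.

## Known limitations

* Presence cells are binary occupancy; abundance information is discarded
  by design, matching the presence/background paradigm.
* The bias surface and ecoregions are smooth low-dimensional fields; real
  effort and ecoregion geometry are rougher, so real-data error bars will
  differ.
* The region-exclusion refit drops occurrences and background candidates
  inside axis-aligned lon/lat boxes; arbitrary polygons would need only a
  containment-test swap.
* Correlations across species are computed on medians with pairwise
  deletion; with few species they carry wide sampling error.
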