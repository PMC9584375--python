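# Methods

`speleosdm` models the habitat suitability of cave-dwelling bats inside
subterranean environments (caves, show caves, mines) from a single
environmental driver: air temperature. The workflow has four stages —
cave geometry, microclimate rasters, ensemble distribution modelling, and
tabular roost-use statistics — plus a synthetic-scenario generator that
carries ground truth for end-to-end validation.

## Spatial model

Each site lives in its own local planar coordinate system (metres). A site
consists of one or two *levels*, each a simple polygon (the cave walls)
with a surveyed centerline graph of stations, and entrance points on the
boundary. Analysis happens on a regular grid (default cell 0.5 m) clipped
to the walls; a cell belongs to the cave iff its center is covered by the
boundary polygon (boundary ties count as inside; row 0 is the top row).

Within-cave distance from the nearest entrance is the shortest path over
the 8-connected lattice of inside cells (diagonal step = cell·√2).
8-connectivity approximates Euclidean path length in narrow corridors far
better than 4-connectivity; the residual overestimate of a straight
oblique path is at most ~8%. Entrances snap to the nearest inside cell
(tolerance 1.5 cells); unreachable inside cells are flagged, never
reported as infinite. Per-level fields are merged on a shared grid with a
priority level winning where levels overlap.

Rasters are exchanged as ESRI ASCII grids (plain text, nodata −9999,
cell-registration in the 6-line header), a format any GIS reads.

## Microclimate rasters

Hourly logger series are reduced to daily means; a calendar day needs at
least 75% of its 24 hourly records, otherwise it is excluded (gaps must
not bias Tmin/Tmax). Each daily point set is augmented with *wall
duplicates*: every logger value is copied onto two points placed along the
perpendicular to the nearest centerline segment, 0.25 m (half a cell)
beyond the wall on each side. This keeps the interpolated surface flat
across the corridor and shields a passage from its neighbours across the
rock.

Interpolation is natural-neighbour (Sibson), implemented as discrete
area-stealing: on a pixel lattice over the grid's bounding box, every
pixel knows its nearest data point (its Voronoi owner) and its distance to
it, and donates its area to each query cell that is closer to the pixel
than the owner is. Donated areas per owner, normalised, are the Sibson
weights up to pixel discretisation (pixel = grid cell by default; an odd
`supersample` refines it). The construction is equivalent to box-clipped
Voronoi insertion. Weights depend only on point geometry, so one weight
matrix serves all ~365 daily fields of a site. Properties preserved:
convexity (output within the input value range), exact reproduction of a
value at a coinciding cell (via an explicit snap; the stolen area of a
coincident query degenerates to zero), constant-field reproduction. Cells
outside the convex hull of the augmented points fall back to nearest
neighbour and are flagged in a QA layer.

Daily fields are summarised per bat activity period — SO (hibernation
start, Sep–Oct), NM (mid-to-end hibernation, Nov–Mar), AM (maternity
start, Apr–May) — into five statistic layers: Tmin, Tmax, Tmean,
Trange = Tmax − Tmin, and population-Tstd, all across *daily mean* fields
(daily surfaces are built first; extremes of hourly values would need a
different reduction, switchable by interpolating hourly tables instead).

Validation is twofold. *Dependent*: leave-one-logger-out — the surface is
rebuilt from the remaining loggers (the held-out logger's wall duplicates
are removed with it, so nothing leaks) and evaluated at the held-out
position; residuals pool over loggers × days into MAE and RMSE.
*Independent*: the surface is compared against spot probe measurements
taken near the animals. Spot probes sit higher than the 2 m logger
height, so independent residuals include a real vertical-gradient
component (≤ 0.9 °C) that is acknowledged but not corrected.

Disturbance recovery: the pre-disturbance baseline (7 days, ≥ 24 h
required) defines the initial stable temperature (IST) as its median;
peak excess is the largest exceedance after the disturbance starts, and
recovery time runs from the peak to the first instant from which the
series stays within a tolerance (default 0.1 °C, the resolution order of
the loggers used in such studies) for ≥ 6 consecutive hours.

## Ensemble distribution modelling

Species × period sets with fewer than 25 occurrences (sum of counts) are
excluded; the threshold is inclusive and applied per species × period,
because models are fitted per period. Records with count > 1 expand to
repeated presence rows — colony size acts as a weight (switchable).
No spatial thinning is applied; instead, global Moran's I is reported as a
clustering diagnostic: occurrence counts are tallied into 2 m aggregation
cells, and I is computed over the occupied cells with inverse-distance
weights truncated at the smallest radius that gives every unit a
neighbour (the standard ensure-a-neighbour threshold), row-standardised;
the z-score uses E[I] = −1/(n−1) and the randomisation variance.

Background (pseudo-absence) points are uniform random inside-cell centers,
10 × presences (min 100), capped at the inside-cell count; sampling
exceeding the domain falls back to with-replacement with a warning.
Presence and background rows are split 75/25 (seeded, disjoint,
exhaustive; |train| = round(0.75 n)).

Seven base-learner families are fitted on the five temperature statistics,
each returning a suitability scorer in [0, 1]:

| family | default |
|---|---|
| CTA | classification tree, depth 4 |
| MARS | forward/backward hinge regression, ≤ 15 terms, GCV pruning |
| GLM | logistic on linear + quadratic terms |
| GAM | logistic on cubic-spline bases (4 knots/feature) |
| ANN | one hidden layer (8 units), seeded |
| SVM | RBF SVC with Platt-style probability calibration on training decision values |
| MAXENT_LIKE | L1-regularised presence/background logistic on linear + quadratic + hinge features |

Each model is weighted by its training ROC AUC (rank-based, ties ½);
models below an AUC floor of 0.5 are dropped, weights renormalised to 1.
Evaluation reports held-out AUC, Cohen's κ at the TSS-maximising
threshold, ten-percentile omission (fraction of test presences strictly
below the 10th linear-interpolation percentile of training-presence
scores), and per-feature contributions: each feature column is permuted
(seeded), and 1 − Pearson r between permuted and intact ensemble scores
(floored at 0) is normalised to percentages.

Binary habitat maps use the TSS-maximising threshold by default
(kappa-max and tenth-percentile alternatives available; ties resolve to
the highest, most conservative threshold; the threshold is recorded in
the map's provenance). Binary maps are summed cellwise with equal weights
— all species treated as equally sensitive — into per-period and
cumulative sensitivity maps; nodata propagates only where every input is
nodata. A weighted overlay is deliberately not implemented.

Models pool all sites' feature tables per species × period (features are
temperature statistics only, never coordinates, so pooling is coherent)
and predict per site.

## Tabular statistics

The packaged site and occurrence tables are keyed by site *name* (site
codes are not stable identifiers across published tables). The two-level
site's levels are summed into one site for all inter-site statistics;
species absent from a site in a period are coded 0.

Rank statistics are tie-aware: Spearman is the Pearson correlation of
midranks with a t-approximation p-value; the Friedman test uses
within-block midranks with the tie-corrected chi-square and Kendall's
W = χ²/(n(k−1)); the paired Wilcoxon signed-rank test excludes zero
differences, midranks ties, and enumerates the exact 2ⁿ sign-flip null
for n ≤ 15 (normal approximation with tie correction above).

The spot-variable analysis is a binomial GLM per species on height above
floor, distance from entrance and spot temperature: predictors with
variance inflation factors above 10 are dropped iteratively (worst
first), then backward elimination removes the predictor whose removal
lowers AIC most until no removal improves it. Note that backward-AIC
retains a pure-noise predictor with probability P(χ²₁ > 2) ≈ 0.16, so
with two noise predictors the exactly-true model appears in ~71% of
simulated replicates — the expected behaviour, verified in the tests.

## Synthetic scenario

No machine-readable raw data accompany studies of this kind, so the
generator emulates the assumed structure and carries ground truth.

Geometry: a seeded meandering centerline (AR(1) heading noise, 2 m steps)
buffered by a jittered half-width (default 4 ± 1 m) into a corridor
polygon; stations every 5 m; entrances on the boundary at the corridor
end(s). The centerline must keep ≥ 4 corridor widths between non-adjacent
passages: a self-touching buffer would merge passages, break the
within-cave distance model and defeat wall-duplicate shielding, so
candidates are redrawn (gradually straightened) until separated.

Thermal regime: T(cell, day) = T_deep + (T_ext(day) − T̄_ext)·e^(−d/λ) + ε
with T_deep = T̄_ext = 9 °C (deep cave air reflects the exterior annual
mean), a pure annual sinusoid of amplitude 8 °C for the exterior,
λ = 50 m and spatially white daily noise σ = 0.1 °C. This puts the
static-climate zone (< 5 °C annual range) beyond ~59 m from the entrance
— a realistic split for mid-size karst caves. Twelve loggers sample their
cell hourly (instrument noise 0.05 °C); their placement follows equal
increments of a 50/50 blend of along-path position and decayed amplitude,
i.e. denser where the thermal gradient is steep but with no unmonitored
deep gaps.

Species and colonies: the default species is a hibernator active in NM
with true suitability ∝ exp(−(Tmin−5)²/2·1²)·exp(−Trange²/2·3²),
max-normalised — a cold mid-hibernation optimum with a penalty on
thermally dynamic sectors, placing the suitable band in the cave interior
where it is identifiable from both directions. Occurrences (default 300)
come from a Thomas-style cluster process: 15 colony parents drawn with
probability ∝ suitability (clusters ≈ field visits × roost patches
accumulating over two seasons), Gaussian offspring dispersion 4 m,
rejection outside the walls. Each cluster has a colony tally scale that
*increases with suitability at its parent* (lognormal around
1 + 6·suitability, capped at 20): larger colonies form in better habitat,
which is what makes count-expansion a meaningful weight. Spot
measurements add a uniform vertical-gradient offset ≤ 0.9 °C plus probe
noise; non-touristic sites receive the flat placeholder of 100 passes.

What the generator does **not** emulate: vertical temperature gradients as
a modelled dimension (only as spot-measurement bias), airflow and
chimney-effect physics, humidity, bat energetics, visitor heat input, and
multi-site pooling with heterogeneous equipment. Passing recovery tests
therefore show that the pipeline recovers a temperature-driven response
from clustered presence data under this idealisation — not that real
cave SDMs attain these scores.

## Numerical choices and problem sizes

- Discrete-Sibson pixel = grid cell (0.5 m); the two-logger corridor test
  reproduces the 1-D linear limit within 0.02 °C at this resolution.
- Stolen-cell radii are capped at the largest query-to-site distance;
  only padding pixels outside the data hull are affected.
- Degenerate inputs fail loudly: < 3 or collinear support points, empty
  periods, single-class labels, all-identical Moran counts, all-zero
  paired differences.
- Ties: AUC counts ties ½; binarization picks the highest tying
  threshold; midranks everywhere else.
- The default scenario (200 m corridor, ~3.5–4 k inside cells, 12
  loggers, one simulated year, 300 occurrence records) runs the full
  pipeline in a few seconds on one CPU; the 20-replicate recovery check
  takes ~2 minutes. These sizes were chosen as the smallest at which the
  static/dynamic zonation, the clustering diagnostic and the recovery
  statistics are all stable.

## Known limitations

- The ensemble's rank fidelity to the true response varies with colony
  placement luck; roughly one seed in six falls below a 0.7 rank
  correlation over all cells even though held-out AUC stays high — an
  inherent property of presence-only sampling from few colonies, not a
  fitting defect.
- Moran's I for a *single* density dome is capped well below the
  multi-colony regime by tally noise between adjacent aggregation cells;
  the diagnostic's z-score, not the raw I, is the robust clustering
  signal there.
- Wall-duplicate shielding fails when two passages approach closer than
  about half the local logger spacing; the generator enforces separation,
  but real multi-level caves need the level-merging path instead.
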