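# Methods

`mosaicpop` estimates gridded ambient population from building footprints.
Its central idea is that the classic building-level estimator

    p_b = A_b * F_b * O_u(b) / 1000

(footprint area in ft², floor count, and an occupancy rate in people per
1000 ft² for the building's use type) should not be evaluated with fixed
inputs when those inputs are uncertain. Instead, use type, floor count and
occupancy are all represented as distributions and propagated by Monte
Carlo, yielding a population *distribution* per building and per grid
cell.

## Population model

**Deterministic baseline.** Each building gets a single use type (known
label, or the residential default), a single floor count (known, or a
default F̄ — 1.5 by default, 2 supported), and the median occupancy rate
of its category and time period. Time-period estimates are combined as a
weighted average (default: day and night, equal weights — the averaging
structure is configurable because no canonical period set exists).
Estimates are scaled by a single factor so they sum to the authoritative
regional total P, then split across 3-arc-second grid cells.

**Monte Carlo estimator.** For buildings without labels, a random-forest
classifier supplies P(U_b = u) over eight use categories (Residential,
Institutional, Retail, Commercial, Transportation, Military, Recreation,
Agriculture) and a random-forest regressor supplies a discrete P(F_b = f).
The two marginals are combined into a joint table by a normalized outer
product, and floors are drawn *conditionally* on the drawn use type. With
independent marginals the conditional equals the floor marginal; the
construction exists so that an externally supplied joint (e.g. from census
constraints) can replace the outer product without changing the sampler.
Each of K draws (default 10,000) samples u, then f | u, then one occupancy
rate per time period from the matching broad-category pool, and evaluates
the estimator above. The draw vector is summarized by its mean and the
5th/50th/95th percentiles (linear interpolation of order statistics).

**Calibration.** One global factor α scales the mean and all quantiles of
every building, preserving relative spread; per-quantile renormalization
is deliberately not performed, so the calibrated P5 and P95 surfaces do
not individually sum to P. `calibrate` supports two bases for α: the sum
of per-building means (`basis="mean"`) or of medians (`basis="median"`).
With right-skewed occupancy the two differ by a few percent; both
conventions are in circulation, and the median basis is the one that makes
the gridded P50 surface sum exactly to P.

**Gridding.** The output grid is 3 arc-seconds (≈90 m) in WGS84, with
edges snapped to integer multiples of the cell size from (−180°, −90°).
Footprints crossing cell edges are split into *molecules*; each molecule
inherits the footprint-area share of its parent building, so per-building
shares sum to 1 and every raster band conserves its building-level sum.
Because the working projection is affine in (lon, lat), degree-space area
ratios equal projected-plane ratios exactly, and shares are computed in
geographic space. The confidence band is 1 − (P95 − P5)/(P95 + P5) per
cell, in [0, 1]; cells with both percentiles zero hold no population and
no spread and are defined as confidence 1.

**Random streams.** Every building's draw stream is derived from
(master seed, CRC32 of the building id), so results are independent of
iteration order and chunking.

## Morphology features

Both attribute models use a footprint-only feature vector in three
families (all lengths in feet):

* *geometric*: area, perimeter, bounding-box extent and area, vertex and
  part counts, perimeter/area, inverse average segment length
  (segments/perimeter), vertices per area, per-segment complexity
  (perimeter/area divided by segment count), and the isoperimetric
  quotient 4πA/P² (1 for a circle). Vertex counts exclude each ring's
  repeated closing vertex and include interior rings.
* *spatial*: nearest-neighbour centroid distance and, per buffer radius
  r ∈ {50, 100, 250, 500, 1000} ft: neighbour count (excluding self),
  observed and expected mean nearest-neighbour distance, their ratio, and
  point intensity. The observed/expected pair follows the Clark–Evans
  convention — omd is the mean nearest-neighbour distance among the
  points inside the disc (focal included) and emd = 1/(2√λ) with
  λ = (count + 1)/(πr²) — because that is the convention under which the
  index averages 1 for complete spatial randomness, which the test suite
  verifies by simulation. The separately reported intensity uses the
  exclude-self count. The feature list also carries an intensity column
  per buffer; upstream descriptions of this family conflate it with the
  nearest-neighbour index, and it is implemented here as plain point
  intensity (count / disc area).
* *contextual*: mean/sd/min/max/cv of neighbouring footprint areas per
  buffer.

Empty neighbourhoods yield NaN sentinels, never zeros; imputation (by
training-set medians stored on the model) happens only in the model layer.
Geometry is projected to a local equirectangular feet system anchored at
the data's centroid — length-true to well under 0.1% at the desk scales
this package targets, and recorded in the run log. For country-scale work
a proper projected CRS should be substituted at the `ProjectionPolicy`
seam.

## Attribute models

Use type: `RandomForestClassifier`, probabilities as *vote fractions*
(1/T times the number of trees voting for each class), not leaf-proportion
averages, so every probability is an exact multiple of 1/T. Floors:
`RandomForestRegressor`, with per-tree continuous outputs rounded to the
nearest integer and clamped to ≥ 1; tallying rounded per-tree values gives
the discrete distribution. The regression route exists because floor-label
inventories rarely cover every class, which rules out direct
classification. Rounding is round-half-to-even (the worked examples
2.09 → 2 and 1.1 → 1 do not disambiguate halves; the convention is tested).
These vote-fraction distributions are relative confidence measures, not
calibrated probabilities; calibration is out of scope.

Model selection is an exhaustive grid over max_depth {10, 20, 30, 40, ∞}
× min_samples_split {2, 5, 10, 20} × min_samples_leaf {1, 2, 5, 10}
(80 candidates) with 3-fold cross-validation, scored by macro-F1
(classifier) or MAE (regressor); a 20% random holdout report is stored
with each model, including for the floor model the MAE/RMSE of the
constant-1.5 and constant-2 heuristics it must beat. A reduced
4-candidate grid is provided for quick runs, and is what the test suite
and reproduction script use. When a building carries several labels the
largest-share label is used.

## Occupancy rates

Occupancy for facility type v and time period t is Beta(α, β) · O_max —
people per 1000 ft², bounded by a practical ceiling O_max. Three layers:

* *Point summaries*: the deterministic baseline uses the median of each
  facility Beta, and a broad category's rate is the mean of its
  subcategory medians.
* *Pools*: the Monte Carlo estimator samples from an empirical pool per
  broad category, built by drawing 10,000 values from each member
  facility's scaled Beta and concatenating (equal draws per facility; no
  prevalence weighting, as none is specified anywhere). The category
  O_max is the maximum of member bounds.
* *Bayesian updating*: (α, β) live on a log-spaced 100×100 grid over
  [0.1, 100]². `update_posterior` multiplies the prior by the product of
  Beta likelihoods of independent observations (computed from sufficient
  statistics, so it is order-invariant and cheap); `jeffrey_update`
  implements the conflation mixture for a single *uncertain* observation
  whose value is represented by a sample set — the appropriate step when
  the input comes from an observation model. A museum observation model
  is built in: pdt = 1000/A · (a·v̄/(d·h̄) + w·p̄) with each observable
  carrying a point, uniform or Gaussian sampling distribution; invalid
  draws (nonpositive area, days or hours) are rejected and resampled.
  The registry is extensible; only the museum form ships because it is
  the only one with a published closed form.

The posterior summary is the mass-weighted mean (ᾱ, β̄). With 2,000
observations from Beta(2, 5), a flat prior recovers (2, 5) to within one
grid step; that tolerance is about two standard errors of the n = 2000
sampling distribution, so the recovery tests average three replicate
datasets rather than betting on a single draw.

## Uncertainty-weighted adjustment and prioritization

Per cell, with percentiles P5 ≤ P50 ≤ P95 (P50 > 0):

    γ = 1 − (P95 − P5)/(P95 + P5)   confidence
    φ = (P95 − P50)/P50             upside deviation (undercount risk)
    δ = (P50 − P5)/P50              downside deviation (overcount risk)
    μ = φ + δ,  η = (φ − δ)/(μ + ε)
    F = 1 + γ(ω_u φ − ω_d δ) + (1 − γ) ω_σ μ η,  clamped

Defaults encode a conservative flood-planning stance: ω_u = 0.30,
ω_d = 0.20, ω_σ = 0.40, ε = 1e−9, clamp [0.2, 2.5]; clamping is applied
per cell. The adjusted surface is F · P50; raster cells with P50 = 0 pass
through as 0, a documented relaxation of the pointwise P50 > 0
precondition.

Hazard prioritization: the composite score is population × risk, with
flood susceptibility classes encoded {0.33, 0.66, 1.00}; unit scores are
means over the cells whose *centers* fall in each admin polygon (an
explicit rule standing in for GIS zonal statistics); units are ranked
descending, ties averaged, units containing no cell centers excluded with
a flag. Rank agreement uses Spearman's ρ — the classic
1 − 6Σd²/(n(n²−1)) when no ties exist, the moment correlation of average
ranks otherwise — with bands high (ρ > 0.75), moderate (0.5, 0.75], low
(0.25, 0.5], near-zero (≤ 0.25). Top-N comparisons re-rank within the
union of any dataset's top-N units.

## Synthetic scenarios

The generator produces everything the pipeline consumes: clustered
rectangular/L-shaped footprints with class-specific area, elongation,
shape and clustering parameters; class-conditional floor counts
(residential mass on 1–2 floors, commercial taller); a day/night Beta
occupancy catalogue with residential night rates above day rates; a
spatially autocorrelated 3-class hazard raster thresholded at area
quantiles; and a Voronoi partition into admin units. The default extent
is 0.05° × 0.05° (a ~60 × 60 cell raster at 3″) with 2,000 buildings, a
60% residential mix, and P = 100,000 — desk scale by design. All
generators are pure functions of (config, seed).

What the fixtures deliberately do *not* emulate: real city morphology,
label noise and spatial label bias, footprint-extraction error, and
fine-grained facility taxonomies. Archetypes are morphologically
separable on purpose, so a passing recovery test (holdout macro-F1 ≥ 0.9
at n = 5000; floor MAE below both constant heuristics) demonstrates that
the learning pipeline extracts the signal the features encode — not that
real building inventories are this separable.

## Numerical choices and degenerate inputs

* Quantiles: linear interpolation of order statistics throughout.
* Calibration rejects a zero estimate sum or nonpositive P; molecule
  splitting rejects footprints outside the grid rather than silently
  renormalizing; grid aggregation conserves every band to 1e−6 relative.
* Degenerate collapse: point-mass attribute distributions plus
  single-valued pools make every Monte Carlo draw exactly equal the
  deterministic estimate, for any K — the test suite checks this
  building-by-building.
* Monte Carlo consistency: draw means match the closed-form expectation
  A/1000 · Σ_i w_i Σ_u P(u) E[f|u] mean(pool_{u,t_i}) / Σ_i w_i within
  three standard errors.
* Problem sizes used by the test suite and the reproduction script —
  5,000 buildings, K = 1,000 for conservation and K = 10,000 for the
  consistency check, the reduced hyperparameter grid with 100 trees —
  were chosen to exercise every path at desk scale; all are configurable
  upward.

## Known limitations

* The local equirectangular projection and degree-space molecule areas
  are appropriate for extents of a few kilometres; country-scale use
  needs a real CRS and equal-area intersections behind the same
  interfaces.
* Vector I/O is GeoJSON and raster I/O is ESRI ASCII grid — both plain
  text and GIS-readable, but without the compression or tiling of binary
  formats.
* Building area is treated as known and static; occupancy pools weight
  member facilities equally; probabilities are uncalibrated vote
  fractions; the eight-category taxonomy coarsens occupancy assignment.
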