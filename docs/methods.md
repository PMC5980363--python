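# Methods

This note records the modeling choices behind `rangeshift`: what each stage
assumes, which knobs matter, what the synthetic study system does and does
not emulate, and where the design was genuinely open.

## Grids, areas and terrain

All rasters are geographic (lon/lat), north-up, cell-center registered.
Cell areas use the spherical formula
`area = (cell_deg · 111.195 km)² · cos(lat)`, i.e. an Earth circumference of
40,030.2 km; a 30 arc-sec cell is ≈ 0.859 km² at the equator and the sum
over a 1°×1° equatorial box agrees with 111.195² km² to < 0.5%. Point-in-cell
lookups use half-open intervals ([west, east) × (south, north]) so every
point belongs to exactly one cell. Nodata propagates: any operation whose
input window touches nodata yields nodata.

Slope and aspect come from Horn's 8-neighbor finite differences; slope is
reported as percent rise and aspect as the downslope bearing clockwise from
north, with flat cells flagged nodata. For modeling, circular aspect is
decomposed into northness/eastness (cosine/sine), with flat cells encoded
as (0, 0) — no facing direction — rather than missing; raw degrees remain
available. The terrain ruggedness index is the mean absolute elevation
difference between a cell and its eight neighbors in a 3×3 window. Escape
terrain is the set of cells with slope ≥ 30°, with no minimum patch size;
distance surfaces are Euclidean distances between cell centers
(`scipy.ndimage.distance_transform_edt`), using the north-south cell size
and the east-west size at the grid's mean latitude, so the transform is
separable and exact. On degree grids, ground cell sizes are derived at each
row's latitude; a constant metric cell size can be supplied for grids built
in ground units.

## Occurrences, background and predictors

Thinning keeps the first occurrence per occupied cell (input order), making
results reproducible for a fixed input file. The train fraction is
`floor(0.70·n)`. The 95% MCP drops the 5% of presences farthest from the
presence centroid (Euclidean, degrees) before taking the convex hull —
neither the MCP literature nor workflow tools pin down the trimming rule,
so the simplest auditable one is used and exposed in config. Background
points (default 10,000) are rejection-sampled uniformly inside the hull on
valid cells and receive the same seeded 70/30 split as the presences so
held-out metrics see both classes.

Collinearity pruning computes Pearson r on the combined presence+background
point table, visits pairs with |r| strictly above 0.7 in decreasing |r|,
and drops the lower-priority member of each still-retained pair. The
priority ranking (climate drivers first: bio1, bio2, bio3, bio4, bio9,
bio15, bio18, then terrain and land cover) is a reproducible stand-in for
the literature-based variable choice an expert would make. Constant
predictors have undefined r and are treated as uncorrelated, with a
warning.

## Model families

All five families share one contract — fit on training rows, predict
suitability in [0, 1] — and background rows are down-weighted to give the
two classes equal total weight in the likelihood-based families.

- **glm_stepwise** — logistic regression with bidirectional AIC stepwise
  selection over standardized linear *and quadratic* candidate terms.
  Quadratics are essential: a linear-only logistic cannot express a
  unimodal (optimum-type) niche response at all.
- **mars** — forward selection of reflected hinge pairs (knots at interior
  quantiles, up to 21 terms), backward pruning by generalized
  cross-validation (penalty d = 3), then a logistic refit on the pruned
  basis. Degree 1 (additive) only.
- **brt** — gradient-boosted trees, learning rate 0.01, depth 3, up to
  2,000 trees with the count chosen by held-out deviance (20% validation
  fraction, patience 25). These are the conventional slow-learning
  settings for ecological boosting.
- **rf** — 500 bootstrap-aggregated trees with per-split feature
  subsampling (√p); suitability is the class-1 vote fraction. Training-row
  scores are taken **out-of-bag**: in-bag votes memorize their rows, and a
  sensitivity=specificity threshold calibrated on them sits in a score
  regime held-out data never reaches (observed TSS 0.13 vs 0.61 with OOB
  scores on the same fit).
- **maxent_like** — maximum-entropy modeling through its penalized-logistic
  equivalence: min-max-scaled linear + quadratic + two-sided hinge features
  (8 knots per predictor), L1 penalty with strength chosen by 5-fold CV
  over C ∈ [0.01, 3]. The path is bounded because unpenalized fits on the
  near-separable hinge expansion are ill-conditioned (and far from any
  maxent-equivalent regularization).

Permutation importance is the mean drop in held-out AUC over seeded
permutations of one predictor column.

## Thresholds, ensembles, change

AUC is the Mann–Whitney statistic with ties counted ½. The binarization
threshold minimizes |sensitivity − specificity| over the union of observed
scores and their midpoints, ties toward the smaller threshold; scores at
the threshold count as present. Thresholds are fitted once on training
scores and frozen for all projections, preventing test leakage and keeping
present and future maps comparable. Model consensus requires k = 3 of 5
families; futures apply model consensus per GCM and then require 2 of 4
GCMs. Aggregating models before GCMs (rather than pooling all 20 binary
maps into one count) keeps the two agreement axes interpretable: a cell
must be ensemble-supported under each climate realization that backs it.

Change categories come solely from the (present, future) bit pair, so
stable + loss equals the present suitable area as an exact cell-count
identity, and the four categories partition the valid grid. Report tables
round half-up to one decimal; percentages are on the present-suitable base,
which is why gains can exceed 100%. Horizon averages are arithmetic means
of areas across the two RCPs with percentages recomputed from the averaged
areas; a companion helper also averages already-printed percentages, since
published tables sometimes do that instead and the two differ in the last
digit.

## The synthetic study system

The generator emulates a high-mountain presence-only study at desk scale:

- **Terrain**: a broad correlated random field (Gaussian-smoothed white
  noise, correlation length 15 cells) plus fine-scale roughness (length
  1 cell, 0.7 field SDs) plus a strong north–south trend (3 field SDs),
  rescaled exactly to 3,300–7,300 m on a 300×300 grid of 30 arc-sec cells.
  The trend is load-bearing: it flattens the elevation histogram (real
  mountain study areas are not Gaussian in elevation) and localizes the
  species band geographically. Without it, either the niche sits
  mid-histogram and background overlap caps every model's AUC near 0.78,
  or it sits in the warm tail and the models never see the warm-side
  decline — fitted responses then become monotone in temperature and
  warming produces no habitat loss at all.
- **Climate**: bio1 = 20 °C − 6.5 °C/km · elevation + correlated noise
  (0.6 °C SD); bio9 sits a 10 °C winter offset below bio1; bio18 (warm-
  quarter precipitation) is a positive structured field with a mild
  orographic term; bio2/3/4/15 are correlated noise around arid-highland
  levels. The generated suite is the asterisked subset a collinearity
  screen retains from the full 19.
- **Riparian network**: the top 3% of a short-wavelength smoothed field — a
  sinuous corridor system of realistic coverage.
- **Virtual species**: suitability = Gaussian(bio1; optimum −9 °C, SD
  1.5 °C) · (1 − e^(−TRI/30 m)) · e^(−dist_riparian/60 km). The optimum
  (≈ 4,460 m) puts the species in the lower-elevation belt with background
  support on both thermal margins; the width was set so the *oracle*
  discriminability (AUC of the true suitability against MCP background)
  lands in the 0.8–0.95 range reported for real mountain-ungulate ENMs.
  Presences (default 976) are drawn with probability proportional to true
  suitability and jittered within their cells.
- **Futures**: 4 pseudo-GCMs × 2 RCPs × 2 horizons. Mean warming +1.6/+2.2
  °C (RCP 4.5, 2050/2070) and +2.5/+4.0 °C (RCP 8.5), warm-quarter
  precipitation factors 0.96/0.94 and 0.92/0.88, plus a per-GCM zero-mean
  correlated noise field (0.3 °C SD). Offsets are CMIP5-era global means
  modestly amplified for high-mountain terrain.

What the generator does **not** emulate: observation bias (roads, effort),
spatial sampling clusters beyond suitability-proportional draws, land-cover
change over time (held fixed, as projection protocols assume), physically
consistent inter-variable climate responses, and downscaling artifacts.
Passing tests therefore demonstrate that the pipeline recovers a known
truth and responds directionally to forcing — not that any real species'
maps would be accurate.

## Problem sizes in the test suite

Unit tests run on miniatures. The recovery experiments use the default
300×300 landscape (10 seeds for driver ranking, with 3,000 background
points — importance ranking is insensitive to background count — and the
full family set on one seed). The directional-response suite runs five
seeds at 150×150 with 700 occurrences: at 100×100 one seed's present
consensus had a warm margin of ~2 cells, so the RCP loss ordering was
decided by noise on ~2 km²; at 150×150 every seed resolves a warm edge of
hundreds of km² and the ordering is stable. Conservation identities are
scale-free and run on a 100×100 fixture.

## Known limitations

- Geographic CRS only; no projected grids or mosaicking.
- The MARS learner is additive (no interaction terms).
- The maxent equivalence is the penalized-logistic form, not the Java
  application; coefficients will differ even where rankings agree.
- The stepwise GLM explores one move at a time and can stop at a local AIC
  optimum on strongly collinear tables (mitigated by the pruning stage).
- Distance transforms use a single east-west cell size at the mean
  latitude; over very tall extents the approximation error grows.
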