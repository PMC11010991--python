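# Methods

## The cellular-neighborhood model

A cellular neighborhood (CN) is a recurring local cell-composition pattern.
For every cell `i` in a spot, the composition window `w_i` is the cell-type
frequency vector over `i` and its `window_size − 1` nearest neighbors by
Euclidean distance on centroid coordinates (default `window_size = 10`:
the center plus nine others; both conventions — "ten nearest cells" vs
"center and nine others" — appear in the literature for this construction,
and this package counts the center as a member). Windows never cross spot
boundaries: TMA cores are physically separate tissues, so a window spanning
two cores would mix unrelated microenvironments. Distance ties at the
window boundary are broken by ascending `cell_id`, which makes the
construction deterministic on gridded or otherwise degenerate geometry;
coordinates are treated as exact and no rim/edge correction is applied.

Windows from all spots are pooled into a single clustering so that CN
identities are comparable across patients, and clustered with mini-batch
k-means (`k = 10` initial clusters) on the raw frequency vectors —
frequencies are already commensurate across types, so no prior scaling is
applied. The fit uses `n_init = 20` restarts, `batch_size = 8192` and
`max_iter = 300` with a fixed `random_state`; these were chosen by a
calibration run on synthetic cohorts (below), where cheaper settings lost
up to 0.1 ARI on half the seeds through poorly converged centroids.
Clusters that end up with zero assigned windows are reported and dropped
before merging (mini-batch k-means already reassigns empty clusters during
fitting, so a post-hoc reseeding pass would second-guess the library fit
for no measurable gain).

### Merging

Initial clusters with similar composition are merged into the final CNs in
one of two modes:

- `explicit_map` — a user-supplied initial-cluster → final-CN mapping,
  applied verbatim. This is the reference mode for reproducing a curated
  labeling, since in practice the "similar biological identity" judgment is
  qualitative.
- `auto_threshold` (default) — average-linkage agglomeration on the cosine
  distance between cluster centroids, cut at `merge_cosine_threshold`,
  with final CNs relabeled 1..n by descending window count.

The default threshold is 0.20. It was fixed by a Monte-Carlo calibration
on synthetic cohorts (16 spots × 2,000 cells, six planted archetypes,
twelve generator seeds): k-means with k = 10 over six true patterns splits
mixed archetypes (e.g. a CD4-heavy vs CD8-heavy halves of the lymphocyte
pattern) into sub-clusters whose centroid cosine distances run up to
~0.16, while distinct archetypes stay ≳ 0.26 apart; 0.20 rejoins the
splits without bridging archetypes (12/12 seeds recover exactly six CNs).
A tighter cut (0.10) left sub-clusters unmerged (7–9 final CNs); looser
cuts (≥ 0.25) started absorbing boundary clusters into the wrong CN.

### Enrichment scores

The enrichment matrix standardizes, per cell type, the mean window
composition across final CNs: entry `(c, t)` is the z-score (population
moments over CNs) of the mean frequency of type `t` within CN `c`. Columns
therefore have mean 0 and unit variance across CNs; a type with zero
variance across CNs scores 0 everywhere (convention, logged). This is the
"cluster map" used to name CNs: a row with CD8/CD4/other-T scores ≳ 2 is a
lymphocyte-enriched neighborhood, and so on.

## Proximity and the spatial score

`nearest_distances` gives, per source cell, the Euclidean distance to the
nearest target-stratum cell in the same spot (`exclude_self` makes a cell
ineligible as its own target when the strata overlap). Spots lacking the
target stratum yield undefined distances, which are excluded — never
imputed — with logged counts. The spatial score of a center cell is the
ratio of its nearest-A distance over its nearest-B distance; per-cell
scores with a zero denominator (coincident centroids) are excluded. The
per-spot score is the **mean of per-cell ratios** by default; the
literature is ambiguous between that and the ratio of mean distances, so
the alternative is exposed as `aggregation="ratio_of_means"`. Scores are
scale-free: multiplying all coordinates by s > 0 leaves them unchanged
(property-tested).

## Outcome statistics

Survival uses the Kaplan–Meier product-limit estimator and the two-group
log-rank test (lifelines; cross-checked in the test suite against a
first-principles implementation of the log-rank formula and hand-computed
product-limit tables). Continuous per-patient covariates are dichotomized
by median split — ties go to "low", deterministically — because published
high/low survival stratifications rarely state their cutoff; a fixed
threshold rule and a short/long-term rule (< 12 months vs > 24 months,
intermediates dropped) are also provided. Group comparisons use two-tailed
two-sample or paired t-tests and one-way ANOVA with Bonferroni-adjusted
pairwise t-tests (adjusted p = min(1, m·p) over m pairs); correlations are
Pearson's r with the t-transform p-value. No multiplicity correction is
applied across the per-CN survival screen — the screen mirrors the common
reporting practice of unadjusted log-rank tests per covariate, with
Bonferroni reserved for within-ANOVA pairwise contrasts. Significance is
reported in the conventional tiers (* < 0.05, ** < 0.01, *** < 0.001).
Degenerate inputs follow logged conventions: identical groups give
statistic 0 and p = 1; a zero-variance comparison with unequal constant
values is reported as certain (p = 0); zero-variance correlation inputs
give undefined r.

## The synthetic cohort generator

The generator emulates what a segmented TMA imaging experiment hands the
analyst, not the imaging itself (no pixels, no segmentation errors):

- **Geometry.** One circular spot per patient (default 64 patients,
  1.5 mm diameter), cell centroids uniform in the disk with no minimum
  spacing — the downstream statistics depend only on relative geometry.
  Default cellularity 1,500–3,000 cells per spot (uniform), a plausible
  density for dense tumor cores; published work rarely quantifies spot
  cellularity, so this is a declared stand-in.
- **Planted regions.** Each spot is partitioned into contiguous regions by
  a planted Voronoi mosaic: `n_region_seeds_per_cn` seed points per
  archetype (default 1, i.e. six regions per spot) scattered uniformly,
  cells assigned to the nearest seed's archetype. Empty regions trigger
  bounded reseeding. An alternative `radial_bands` layout (equal-area
  annuli, archetypes cycling outward) exercises layout-independence.
- **Archetypes.** Six default composition rows over the eight types sketch
  canonical tumor-microenvironment compartments: pure stroma, bulk tumor,
  a lymphocyte-enriched region (CD4/CD8/other-T/B mix), a perivascular
  region, a macrophage niche, and a reactive (immune-infiltrated) stroma.
  Each row has a distinct dominant component. That separation is a stated
  precondition of the recovery analysis, not a claim about tissue: with
  10-cell windows, heavily overlapping compositions push even the
  Bayes-optimal window classifier below ARI 0.8, so recovery tests on
  near-identical archetypes would measure multinomial noise, not the
  algorithm. Passing recovery tests here show the pipeline finds planted
  structure when it is findable; they do not show that real CNs are this
  well separated.
- **Marker emission.** Two log-normal channels per marker — negative
  median 5 a.u., positive median 60 a.u., both σ = 0.3 in log space
  (≈ 4σ log-separation). A cell draws the positive channel for DAPI
  (every cell is nucleated) and its type's defining markers, the negative
  channel otherwise. Default gating thresholds sit at the log-midpoint
  (≈ 17.3 a.u.), giving ≥ 99.9% gating recovery; real channels bleed and
  overlap far more, so gating accuracy on real data is an upstream QC
  question this package does not answer.
- **Survival.** Time-to-event is exponential with rate
  `survival_baseline · exp(survival_beta · f)` where `f` is the patient's
  true risk-archetype frequency (defaults: baseline 0.03/month ≈ 23-month
  null median, matching an aggressive-cancer cohort; β = 3; risk
  archetype = the lymphocyte region). Censoring is administrative: with
  probability `censoring_rate` (default 0.2) a patient gets a cutoff
  uniform on (0, 60) months; `event = 1` iff death precedes any cutoff.
- **Determinism.** All randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawning (one child per patient, one for
  survival); identical configs give byte-identical tables, and no global
  random state is touched.

## Calibrated expectations

Quantities asserted by the test suite were frozen from Monte-Carlo
calibration runs *before* the corresponding tests were written:

- **Planted-CN recovery** (16 spots × 2,000 cells, defaults): exactly six
  final CNs in 12/12 generator seeds; cell-level ARI vs the planted
  regions 0.77–0.91 (mean 0.86). The residual gap to 1 is dominated by
  cells near region borders, whose windows genuinely mix archetypes.
- **Null log-rank calibration**: with β = 0, the median-split log-rank on
  64-patient cohorts rejected at α = 0.05 in 4.0% of 500 seeds.
- **Planted-hazard direction**: with β = 3, the high-frequency group had
  the shorter KM median in 93.8% of 400 seeds; the test threshold is 0.88
  (central rate minus three binomial σ at the test's n = 200).

These simulations use per-patient risk frequencies drawn from Beta(2, 8),
matching the scale and spread of area fractions that one-region-in-six
Voronoi mosaics produce, so the survival calibration runs in seconds
instead of regenerating full imaging cohorts.

## Problem sizes and numerical conventions

The standard verification scale is 16 spots × 2,000 cells (~32,000
windows; the full pipeline takes ~1 s, the complete default cohort of 64
patients ~11 s on one CPU). Composition rows sum to 1 within 1e-9;
archetype rows are validated to the same tolerance. kNN queries use a
k-d tree with an exact tie-resolution pass (ball query at the boundary
radius, then lexicographic (distance, cell_id) ordering), verified against
O(n²) brute-force oracles. Voronoi polygons come from the GEOS Voronoi
diagram clipped to the spot disk; the tessellation property (polygon areas
summing to the disk area) is tested to 0.1% — the residual is the polygonal
approximation of the circular boundary.

## Known limitations

- Cell centroids are uniform within regions; real tissue has packing
  constraints, density gradients, and segmentation artifacts the generator
  does not model, so distance distributions are idealized.
- The emission model is per-marker independent; real spectral overspill
  and autofluorescence correlate channels.
- The auto-merge threshold was calibrated on the default archetypes; very
  different composition geometries may need a different cut, or the
  explicit merge map.
- One spot per patient: the package keys everything by `patient_id` and
  does not model multi-core patients or intra-patient heterogeneity.
- No Cox modelling or optimal-cutpoint search; survival screening is
  deliberately the simple median-split log-rank design.
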