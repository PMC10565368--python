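# Methods

## The analysis model

The pipeline treats a monitoring dataset as a long-format table of counts
keyed by (site, station, species, period), where a period is one 2-week
sampling interval (m = 26 periods per year; the default design covers 2
years, T = 52). Counts are interpreted as *activity* — a compound of
abundance and per-individual behaviour — not as abundance estimates; every
downstream statement is therefore about activity dynamics.

### Land-cover scores

Per-site proportions of seven land-cover classes (forest, agriculture,
urban, grass, sand, freshwater, miscellaneous) are renormalized to sum to
one over land (coastal buffers can include ocean), transformed by
arcsin(√p) to stabilize variance near the simplex boundary, and decomposed
by covariance PCA (column-centred, unscaled — the `prcomp` default).
Renormalization happens *before* the transform; the alternative order is not
meaningfully different for interior compositions but the choice is fixed for
reproducibility. Because PCA signs are arbitrary, they are pinned: PC1 has a
positive forest loading (forested sites score high), PC2 a positive
grass+agriculture loading (rural high, urban low), so slopes of responses on
the scores are comparable across datasets and runs.

### Conditioning

Station-level counts are capped at `threshold` (default 500) before any
aggregation — the cap targets one-trap mass-recruitment outliers, which
summation would smear into site totals. Thresholding is idempotent; it does
not commute with aggregation (capping site sums is a different operation),
which is why the order is fixed. Stations are then summed to sites, sites to
land-cover groups where needed; both are exact integer sums, with absent
stations contributing zero under a logged warning.

Rarefaction equalizes sampling effort: each site's species × period matrix
is resampled without replacement to a common target (the minimum site
total), drawing from the pooled cells so the joint species–time structure is
preserved in expectation (each cell's expectation is n_cell·target/N, the
multivariate hypergeometric mean). Metrics are computed on each of
`n_rarefaction_reps` replicates (default 100) and averaged; the replicate
count is a precision knob, not a scientific parameter — replicate means
converge at rate 1/√n_rep.

### Variability metrics

* Functional CV: sample standard deviation (n−1) over mean of the
  community-total series. Requires a positive mean; scale-invariant.
* Compositional (temporal beta diversity): time steps are rows after a
  Hellinger transform (square root of within-step relative abundances);
  columns are centred; BD_total = SS_total/(T−1) and SCBD_j = SS_j/SS_total.
  Steps with zero total are dropped with a warning. SCBD sums to one and is
  additionally summed by alien status (native / alien / uncertain).
* Richness: observed; rarefied (mean observed richness over replicates);
  extrapolated Hill q = 0 from site-level abundance frequency counts, with
  f̂₀ = ((n−1)/n)·f₁²/(2f₂) (or the f₂ = 0 fallback ((n−1)/n)·f₁(f₁−1)/2)
  and the accumulation curve extended to double the sample size (endpoint
  m* = n). The doubling endpoint is a knob; site-level (not station-level)
  frequency counts are used.

### Decomposition

Each series is fitted by OLS on {1, t, sin(2πt/m), cos(2πt/m)} — a linear
trend plus a first-order annual Fourier term, i.e. seasonality as a single
sine wave. With only two annual cycles, higher harmonics invite overfitting;
`fourier_order` is exposed but K = 1 is the supported default. t is the
integer period index, not a calendar date — the cadence is fixed by design.
The trend component carries the intercept (a constant shifts no variance);
the remainder has mean zero at the fitted points; missing observations are
excluded from the fit but the deterministic components are still evaluated
there. The fit refuses series with fewer than 5 usable points, spanning less
than one annual cycle, or with a rank-deficient design.

Component variances use the population (1/n) denominator: the components
are deterministic functions evaluated on the whole observation window, and
this makes a pure sinusoid over whole cycles come out at exactly A²/2.
Relative variances (component variance over summed component variance) are
identical under either denominator, so this choice affects only the absolute
numbers. CV, beta diversity and synchrony keep the sample (n−1) convention
of their defining frameworks.

Synchrony follows Loreau & De Mazancourt: φ = var(Σᵢxᵢ)/(Σᵢ sd(xᵢ))², which
is 1 for perfectly synchronous and 0 for perfectly compensating dynamics and
is scale-free. Because "standardizing" input series is redundant for a
scale-free index, the package emits synchrony both on raw (replicate-mean)
series and on fitted seasonal components; the seasonal-component variant is
the headline number for the status × group comparison.

### Inference

Candidate OLS models over {∅, PC1, PC2, PC1+PC2} are ranked by
AICc = AIC + 2k(k+1)/(n−k−1), with k counting all estimated parameters
including the error variance (this accounting is stated to avoid off-by-one
ambiguity; the correction term for the PC1-only model at n = 24 is 1.2).
Candidates with n−k−1 ≤ 0 are skipped with a warning; constant responses are
rejected.

Moran's I on the selected model's residuals uses row-standardized inverse
Euclidean distance weights by default (a k-nearest-neighbour scheme is
available); coincident sites get a minimum-distance floor. The permutation
test is two-sided around the null expectation E[I] = −1/(n−1), with
p = (1 + #{|I_perm − E[I]| ≥ |I_obs − E[I]|})/(n_perm + 1) and 999
permutations by default. The weighting scheme is a genuine free choice — the
statistic's magnitude depends on it — so it is a config knob, and the test
is used only as a screen for whether spatially structured models are needed.

The paired species comparison screens the differences with Shapiro–Wilk
(normality flag at p > 0.05) and reports the two-sided Wilcoxon signed-rank
test: zero differences dropped, mid-ranks for ties, exact null distribution
for n ≤ 25 without ties, otherwise the normal approximation with continuity
correction. The exact path is verified in the tests against full 2ⁿ sign
enumeration.

### Group comparison

Sites are ranked by PC1; the top `n_per_group` (default 8) are forested, the
bottom 8 developed, the middle excluded — boundary ties resolve to the
lexicographically smaller site id, deterministically. Species are retained
iff present in both groups and their combined total exceeds `min_total`
(default a strict > 100; the ≥ reading is available via
`min_total_inclusive`). Each retained species' two group series are rarefied
to their common minimum, fitted, and the relative seasonality variances
averaged over replicates to give one paired value per species.

Responses split by rarefaction status deliberately: the natural log of total
site activity is modelled *before* rarefaction (rarefaction would erase
exactly the signal of interest), while all variability metrics are modelled
*after* it (they would otherwise be confounded by effort).

## The synthetic-data generator

No generative model is prescribed by the field protocol this package
emulates; the generator is a documented stand-in whose purpose is to give
every pipeline stage a ground-truth recovery test. It emulates a 24-site,
3-station, 52-period, 40-species survey:

* **Landscape.** Forest proportions are spread evenly over [0.05, 0.95]
  (the gradient always spans nearly the full range); the remaining mass is
  Dirichlet-split over the other six classes with agriculture and urban
  dominating. Coordinates live on a 30 × 100 km projected plane; with
  `forest_gradient` (default on) forest increases south-to-north, mirroring
  a real island gradient and making the Moran machinery exercise a
  spatially structured landscape.
* **Species pool.** Species statuses are drawn with probabilities
  (0.5, 0.2, 0.3) for native/alien/uncertain. Species are forest- or
  developed-affiliated (natives with probability 0.8, aliens 0.2, uncertain
  0.5); forest-affiliated species share a concentrated von Mises phase
  (κ = 8), developed-affiliated phases are uniform, so phase mismatch — and
  hence lower community synchrony — emerges in the developed assemblage
  rather than being hard-coded.
* **Rates.** log-mean activity of species i at site s and period t is
  b_is + A_is·sin(2πt/m + φ_i) + β_i·t, with per-species baselines
  log-normal (meanlog log 0.5, sdlog 2.0 — a realistic dominance structure
  with a long rare tail), `baseline_gain` = −1 tilting overall activity
  toward developed sites, log-amplitude Normal(log 0.6, 0.4) plus
  `seasonal_gain` (default 1.5) times centred forest cover — the coupling
  the pipeline is asked to recover — and trend slopes Normal(0,
  `trend_sd` = 0.004) per period.
* **Counts.** The site-level count is negative-binomial with that mean and
  size `dispersion` = 5 (overdispersed, as trap counts are; Poisson in the
  dispersion → ∞ limit used by the law-of-large-numbers tests), then split
  multinomially over stations with per-site Dirichlet(8) weights — so
  station-to-site summation is lossless by construction.
* **Scenario knobs.** `seasonal_gain = 0` decouples seasonality from land
  cover (the calibration null). `affinity_gain` (default 0) adds
  composition turnover — species rarer away from their preferred habitat.
  It is off by default deliberately: turnover interacts with the phase
  structure (forest sites would be dominated by phase-aligned species) and
  induces a seasonality–gradient relationship even at `seasonal_gain = 0`,
  so it must be a scenario, not part of the null conditions.

What the generator does **not** emulate: detection/occupancy processes,
weather-driven interruptions and missing sampling events, within-site
habitat heterogeneity between stations beyond a static multinomial weight,
species interactions, non-sinusoidal or multi-peaked phenology, and real
spatial autocorrelation in species composition. Passing recovery tests
therefore show that the estimation machinery is correct and calibrated under
the stated model, not that the model captures every property of field data.

## Numerical choices

* All randomness flows from explicit seeds through `numpy` `SeedSequence`
  streams with fixed per-stage keys, so each stage is independently
  reproducible and full reruns are byte-identical.
* Rarefaction uses `Generator.multivariate_hypergeometric`; replicate counts
  (default 100; 20 in the repeated-seed calibration runs, where the
  between-seed variance dominates the replicate noise) trade precision
  against runtime.
* Degenerate inputs fail loudly and specifically: zero-mean CV, constant
  composition, infeasible rarefaction targets, rank-deficient designs,
  all-zero paired differences, zero-variance responses and residuals each
  raise a typed error; the pipeline catches, logs and skips where a partial
  result is meaningful (e.g. a constant response is simply not regressed).
* The constant-series flag in `component_variances` uses a scale-aware
  tolerance ((10⁻¹² × series scale)²) because float rounding leaves O(ε²)
  variance in exactly-constant fits.
* Moran permutations are vectorized (all permutations in one einsum), which
  is what makes the 1000-run calibration test affordable.

## Known limitations

* The Hellinger/BD machinery assumes count (or at least non-negative)
  composition data; it is not meaningful for already-transformed inputs.
* Only K = 1 Fourier seasonality is tested; `fourier_order > 1` is exposed
  but with two annual cycles the extra harmonics are weakly identified.
* The AICc candidate set is fixed to the four PC1/PC2 combinations; it is
  not a general model-selection engine.
* With strongly spatially structured synthetic gradients the Moran screen
  fires by design; the package deliberately stops at screening and does not
  fit spatial GLS models.
* Temperature series are taken as given inputs (site, period, air/soil
  columns) and only passed through the same decomposition; no sensor-gap
  handling is attempted.
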