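# antseasons

Analysis pipeline for the temporal variability of insect (ant) community
activity across an anthropogenic land-cover gradient, built around biweekly
trap-count time series.

Passive-trap monitoring networks record community *activity* — individuals
intercepted per trap per sampling period — at sites spanning a gradient from
contiguous forest to urban and agricultural land. This package quantifies how
the *components* of that temporal variability change along the gradient:
whether communities in disturbed landscapes lose their seasonal rhythm and
become dominated by stochastic fluctuation. It is aimed at community
ecologists working with fine-resolution (sub-annual) count monitoring data,
and ships a fully parameterized synthetic-data generator so every stage can
be validated against known ground truth.

## The method

1. **Land-cover gradient.** Per-site proportions of seven land-cover classes
   are renormalized over land, arcsine-square-root transformed, and reduced
   by covariance PCA. PC1 is oriented so high scores mean forested, low
   scores developed; PC1/PC2 are the regression predictors.
2. **Count conditioning.** Station-level counts are capped at a threshold
   (default 500) to tame single-trap recruitment outliers, summed to site
   level, and rarefied — individuals drawn without replacement from the
   pooled species × period cells (multivariate hypergeometric) — to the
   minimum site total, removing mean–variance sampling artefacts.
3. **Variability metrics.** Per rarefied replicate and site:
   functional variability CV = sd(y)/mean(y) of the community-total series;
   compositional variability BD = SS_total/(T−1) of the Hellinger-transformed
   species × time matrix, with species contributions SCBD_j = SS_j/SS_total
   (summing to 1, also totalled by native/alien/uncertain status); richness
   observed, rarefied, and Chao-style extrapolated (Hill number, q = 0).
4. **Decomposition.** Each series is regressed on
   y(t) = β₀ + β₁t + γ_s sin(2πt/m) + γ_c cos(2πt/m) + ε(t) with m = 26
   biweekly periods per year (annual Fourier term, K = 1), yielding additive
   trend, seasonal and remainder components and their absolute and relative
   variances.
5. **Inference.** Each site-level response is related to PC1/PC2 by OLS with
   AICc model selection over {∅, PC1, PC2, PC1+PC2}; residuals of the
   selected model are screened for spatial autocorrelation with a Moran's I
   permutation test (999 permutations).
6. **Group comparison.** Sites are partitioned by PC1 into forested /
   developed / excluded thirds; species shared between groups with combined
   totals above a filter are rarefied to their between-group minimum, their
   relative seasonality variances compared pairwise (Shapiro–Wilk screen,
   Wilcoxon signed-rank), and Loreau–De Mazancourt synchrony
   φ = var(Σᵢxᵢ)/(Σᵢ sd(xᵢ))² computed per status × group.

## Worked example

```python
import antseasons as ans

cfg = ans.SimulationConfig(seed=1)          # 24 sites x 3 stations x 52 periods x 40 species
bundle = ans.run_full_analysis(cfg, ans.PipelineConfig())

ve = bundle.scores.variance_explained
print(f"PC1/PC2 variance explained: {ve[0]:.1%} / {ve[1]:.1%}")

sel = bundle.regression_table.set_index("response")
for resp in ("log_total_activity", "cv", "bd_total", "rel_seasonal", "rel_remainder"):
    row = sel.loc[resp]
    print(f"{resp:20s} model={row['selected']:8s} R2={row['r_squared']:.2f} "
          f"coef(PC1)={row['coef_PC1']:+.3f} Moran p={row['moran_p']:.3f}")

gc = bundle.group_comparison
print(f"retained species: {len(gc.species_table)}")
print(f"Wilcoxon signed-rank p = {gc.wilcoxon.wilcoxon_p:.2e}, "
      f"median paired difference = {gc.wilcoxon.median_difference:+.3f}")
```

prints

```
PC1/PC2 variance explained: 72.2% / 12.0%
log_total_activity   model=PC1      R2=0.90 coef(PC1)=-0.389 Moran p=0.002
cv                   model=PC1      R2=0.84 coef(PC1)=+0.243 Moran p=0.225
bd_total             model=PC1      R2=0.91 coef(PC1)=+0.109 Moran p=0.009
rel_seasonal         model=PC1      R2=0.72 coef(PC1)=+0.315 Moran p=0.366
rel_remainder        model=PC1      R2=0.74 coef(PC1)=-0.319 Moran p=0.614
retained species: 34
Wilcoxon signed-rank p = 3.82e-07, median paired difference = +0.208
```

Read: total activity is higher at developed sites (negative PC1 slope), both
facets of temporal variability increase with forest cover, the seasonal share
of variance rises with forest cover while the stochastic share falls, and the
same species are individually more seasonal in the forested group (positive
median paired difference). In this synthetic landscape the forest gradient is
spatially structured, so a couple of responses trip the Moran screen — with
field data a significant screen would motivate a spatially explicit model.

The same stages are available as CLI subcommands
(`antseasons simulate | landcover | prepare | metrics | decompose | groups |
run-all | temperature`), with `--threshold` exposing the outlier-cap
sensitivity sweep.

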