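# sdmstack

Stacked species distribution models for mapping richness and delineating
floristic regions from presence-only occurrence records.

Herbarium-style occurrence data are presence-only, spatially sparse, and
collected where people went rather than where species live. `sdmstack` is
a desk-scale, fully seeded implementation of the standard pipeline that
turns such records into defensible diversity maps and bioregionalizations,
aimed at macroecologists and biodiversity informaticians who want every
stage testable against known truth:

1. **Predictors** — Spearman-based collinearity pruning (|ρ| < 0.75 kept,
   priority-ordered) and a per-predictor chi-square test of whether
   collection localities represent the domain's environmental space.
2. **SDMs** — maximum-entropy presence-background models, written as the
   equivalent L1-penalized log-linear density over background cells, with
   feature classes set by record count (5–10 linear, 11–14 quadratic,
   ≥ 15 hinge) and rank AUC for discrimination.
3. **Null model** — each species' AUC is tested against AUCs of models
   refit to random subsamples of the *observed collection localities*, so
   collection bias is absorbed into the null; a species is kept when its
   AUC exceeds the empirical 95th percentile.
4. **Stacking** — per-species thresholds (sensitivity = specificity or
   sum-maximization for 5–9 records; the 10-percentile training-presence
   threshold for ≥ 10) build a cells × species presence/absence matrix
   whose row sums are species richness S.
5. **Richness drivers** — nine-term cubic trend surface
   (LON, LAT, LON², LON·LAT, …, LAT³), variation partitioning of adjusted
   R² into pure environment / pure space / shared / unexplained, forward
   stepwise regression with standardized betas, Moran's I residual
   diagnostics.
6. **Bioregionalization** — richness-independent beta-sim turnover,
   β_sim = min(b,c)/(min(b,c)+a), UPGMA clustering, and selection of the
   number of regions by minimizing summed indicator-species (IndVal)
   p-values over k on repeated cell subsamples.
7. **Relative environmental turnover** — non-metric multidimensional
   scaling of the beta-sim matrix (Kruskal stress-1, 100 starts),
   permutation-tested environmental vectors, and per-region Getis-Ord Gi*
   (|z| > 2 flags a region whose environment departs from the domain).

A first-class synthetic module generates virtual worlds — smooth
autocorrelated predictor surfaces, Gaussian-niche virtual species,
contiguous regions with controlled species-pool overlap, and road-corridor
collection bias — so recovery of niches, richness drivers and regions can
be verified against generating truth.

## Worked example

```python
from sdmstack import (make_world, collect, prune_predictors, bias_test,
                      fit_sdm, NullModel, stack, optimal_k)

world = make_world(n_lon=40, n_lat=30, n_predictors=8, n_species=200,
                   k_regions=4, seed=11)
occ, localities = collect(world, effort=5000, bias_strength=1.0, seed=12)
print(f"{len(occ)} species collected over {len(localities)} localities")

env, report = prune_predictors(world.env, rho_max=0.75)
print(f"kept {len(env.names)} of {len(world.env.names)} predictors")
print(bias_test(env, localities))

occ, dropped = occ.filter_min_cells(5)
fits = [fit_sdm(occ.cells(sp), env, species_id=sp) for sp in occ]
nm = NullModel(env, localities, n_null=199, seed=13)
sig = [f for f in fits if nm.test(f).significant]
print(f"{len(sig)} of {len(fits)} species significantly non-random")

pam = stack(sig)
print(f"richness range: {pam.richness.min()}-{pam.richness.max()}")

reg = optimal_k(pam, k_range=range(2, 9), subsample_size=300,
                n_repeats=2, n_perm=99, seed=14)
print(f"optimal number of regions: {reg.chosen_k}")
```

Output (about ten minutes, dominated by the null-model refits):

```
184 species collected over 804 localities
kept 8 of 8 predictors
BiasReport(3/8 predictors biased at alpha=0.05)
134 of 146 species significantly non-random
richness range: 0-61
optimal number of regions: 4
```

Reading it: of 200 simulated species, 184 yield records and 146 occupy the
five-cell minimum; road-biased collecting leaves 3 of 8 predictors with
environmentally non-random localities; the null model discards 12 species
whose apparent habitat signal is explainable by collecting patterns alone;
stacking the rest maps richness from 0 to 61 species per cell; and the
summed-p criterion recovers exactly the four regions the world was built
with.

The same pipeline runs from the command line over a directory of
plain-text artifacts:

```sh
sdmstack --outdir runs/demo --seed 11 run-all
```

with per-stage subcommands (`simulate`, `prune`, `bias-test`, `fit-sdm`,
`nulltest`, `stack`, `richness-drivers`, `regionalize`, `ret`), cached
intermediates and a seed-recording manifest.

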