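# biodivmap

Joint species distribution modelling and biodiversity mapping from point
community samples (presence–absence) plus remote-sensing raster
covariates. The pipeline fits a regularized multivariate-probit JSDM
(optionally with a small neural feature network and a spatial trend
surface), tunes it by random search + k-fold cross-validation, predicts
per-pixel occurrence probabilities across a landscape, and derives
species richness, t-SNE community-composition axes, and probabilistic
(Poisson-binomial) site-irreplaceability maps. A synthetic
landscape/community generator makes every stage testable at desk scale.

## Modules

| module | what it does |
| --- | --- |
| `biodivmap.synthcommunity` | synthetic landscapes (Gaussian random fields), sparse nonlinear species responses with calibrated prevalence, sampling designs with paired traps, Bernoulli incidence simulation |
| `biodivmap.tables` | presence calling from barcode-coverage tables (> 50% rule), incidence filtering (≥ 6 samples), iterative VIF covariate reduction, 75/25 train–test split |
| `biodivmap.jsdm` | Monte Carlo multivariate-probit likelihood with analytic gradients, linear/MLP feature networks, low-rank species loadings, polynomial trend surface, proximal-Adam elastic-net fitting, rank-based AUC |
| `biodivmap.tune` | random hyperparameter search, fivefold CV, holdout evaluation (explanatory vs predictive AUC), whole-data variability protocol |
| `biodivmap.xai` | permutation importance (drop in explanatory AUC) and Friedman-H² pairwise interaction strength |
| `biodivmap.maps` | chunked raster prediction (bit-identical to unchunked), AUC-based species filtering, thresholded richness, t-SNE composition maps |
| `biodivmap.irreplace` | exact Poisson-binomial PMF, per-species alpha pivotality and combined beta irreplaceability per pixel, block aggregation for large rasters |
| `biodivmap.pipeline` / `biodivmap.cli` | end-to-end orchestration, YAML config, provenance manifest with per-file hashes |

## CLI

Every stage is a subcommand; `run` executes them all and writes a
`manifest.json` with sha256 hashes of every artifact (a rerun with the
same config is byte-identical):

```sh
biodivmap run --out out/demo --seed 0            # built-in demo config
biodivmap simulate --out out/demo                # ... or stage by stage
biodivmap prep --out out/demo
biodivmap tune --out out/demo
biodivmap fit --out out/demo
biodivmap evaluate --out out/demo
biodivmap importance --out out/demo
biodivmap map --out out/demo
biodivmap irreplace --out out/demo
```

Pass `--config my.yaml` to override defaults (see
`biodivmap.pipeline.DEFAULT_CONFIG` for the schema: grid size, species
counts, thresholds, hyperparameter search space, CV settings, seeds).
Outputs include per-species probability GeoTIFFs, `richness.tif`,
`tsne_1.tif`/`tsne_2.tif`, `irreplaceability.tif`, CV tables, importance
tables and the fitted model archive (`model.jsdm`).

## Notes

- Raster I/O is a minimal GeoTIFF reader/writer built on `tifffile`
  (standard geo tags + a JSON band-name payload); files round-trip
  exactly through `biodivmap.geotiff`.
- All fitting is numpy with hand-written gradients; no GPU or autodiff
  framework is required. Every generator, fit and map is a pure
  function of its arguments and a seed.
- Beta irreplaceability is exact and O(species × pixels²); use the
  `block_size` option to pool pixels into planning units on large
  landscapes.
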