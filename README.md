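# ippm — integrated point process models for multi-stream presence data

`ippm` implements an end-to-end analysis pipeline for presence-only species
distribution modeling that fuses a structured survey stream ("nest" records)
with an opportunistic, effort-biased stream ("ebird" checklists):

- **`ippm.synthetic_data`** — seeded synthetic landscapes (static and
  per-year dynamic covariate layers, vector lakes/roads/settlements/trees
  with exact distance layers), a Matérn × AR1 latent field, and both point
  streams drawn from the generative model (the opportunistic stream from a
  thinned intensity).
- **`ippm.covariates`** — layer engineering: surface-water reclassification,
  maximum composites, Horn slope, exact Euclidean distances, the saturating
  distance kernel `1 − exp(−d/μ)`, binary distance classes, moving-window
  scale summaries (30 m pixel / neighbors / 90–750 m radii), road density,
  checklist-effort filtering, standardization and design assembly.
- **`ippm.ppm_lasso`** — Berman–Turner quadrature schemes and downweighted
  Poisson regression approximating the inhomogeneous Poisson point process,
  with L1 (LASSO) regularization, per-covariate scale optimization and
  cross-validated candidate-model comparison.
- **`ippm.random_field`** — a lattice SPDE (Matérn ν = 1) Gaussian Markov
  random field, exactly diagonalized by the 2-D DCT (fast sampling and exact
  log-determinants), combined with a stationary AR1 process over years via
  Kronecker precision; penalized-complexity priors on range and sd.
- **`ippm.integrated_fit`** — the joint model: shared log intensity
  `η = β₀ + Xβ + u(s,t)` across streams, log-linear thinning
  `log b = δ₀ + Zδ` on the opportunistic stream, Gaussian coefficient
  priors, MAP + nested-Laplace inference with Gaussian credible intervals.
- **`ippm.predict_assess`** — annual intensity surfaces, SEDI-optimal
  suitability thresholds, relative-abundance indices with conditional
  bootstrap intervals, and block-mean/min-max presentation aggregation.
- **`ippm.validation`** — temporal and spatial block cross-validation,
  variogram-informed block sizing, Mann–Whitney AUC, buffered checklist
  evaluation, and the with/without-opportunistic-stream ablation.
- **`ippm.io_core` / `ippm.cli`** — grid geometry, GeoTIFF and ESRI ASCII
  raster I/O, point CSV I/O, YAML configuration and the staged pipeline.

## CLI

The pipeline runs staged: `simulate → prepare → select → fit → predict →
validate`, each stage writing machine-readable artifacts (CSV/JSON/ASCII
grid) plus a seeded log. Identical config + seed reproduce identical
outputs.

```sh
ippm run --config config.yaml --outdir out/ --seed 7
# or a single stage (runs its prerequisites):
ippm fit --config config.yaml --outdir out/
```

A minimal config needs a `grid` section (origin, cell size, dimensions,
inclusive year range) and lists of ecological / observation covariates; see
`tests/test_cli.py::_demo_config` for a complete working example.

## Notes on method fidelity

- The triangular SPDE mesh is replaced by a regular-lattice discretization
  at (a coarsening of) the analysis grid; the range convention is the usual
  "correlation ≈ 0.1 at distance ρ" (κ = √8/ρ) and the marginal variance is
  calibrated exactly at interior cells.
- Inference is empirical-Bayes flavored MAP + nested Laplace, not full
  INLA: posterior medians and 2.5/50/97.5 quantiles come from the Gaussian
  approximation at the joint mode.
- Checklist-effort covariates enter the observation design as spatial
  surfaces of typical local effort, which keeps the thinned point process
  likelihood well-posed.
- Bootstrap abundance intervals are conditional (hyperparameters held at
  their fitted values per replicate).
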