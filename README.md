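# seaway

Presence-only maximum-entropy species distribution modelling for coastal
acoustic-telemetry data, with a fully synthetic domain generator so every
stage of the pipeline runs reproducibly from a single integer seed.

The pipeline mirrors a common marine SDM workflow:

1. **`seaway.synthetic_domain`** — seeded synthetic shelf domains (bathymetry
   bounded by the 200 m isobath, latitude affine in row index), seasonal
   near-bottom ocean fields (temperature, oxygen saturation, currents),
   virtual species with known response coefficients, and simulated acoustic
   telemetry at fixed hydrophone sites.
2. **`seaway.occurrence`** — detection-day accounting (summed gaps between
   consecutive same-site detections), seasonal aggregation to at most one
   presence record per hydrophone per season (>= 1 detection-day), and
   merging of month-referenced supplementary reports.
3. **`seaway.covariates`** — depth-class cost surfaces (1 / 5 / 10 for
   10–200 m / 0–10 m / > 200 m), accumulated least-cost distances to the
   spawning and overwintering attractors, ordinary kriging (auto-fitted
   spherical variogram) of coarse ocean-model points onto the 1 km grid, and
   sample-matrix assembly with the month/season matching rules.  The
   overwintering attraction covariate is used only in autumn/winter models,
   the spawning attraction only in spring/summer.
4. **`seaway.maxent_engine`** — the penalized maximum-entropy density-ratio
   model: linear/quadratic/product/hinge/threshold features scaled to [0,1],
   per-feature L1 penalties `r * b_class(m) * sd / sqrt(m)`, proximal
   gradient fitting with Barzilai–Borwein steps (monotone in the penalized
   objective), and raw / cumulative / logistic output transforms.
5. **`seaway.evaluation`** — 10-fold cross-validation over presences with a
   shared background, ROC/AUC against pseudo-absences, equal
   sensitivity–specificity thresholds, binomial omission tests, permutation
   importance, jackknife gain, and k-sample median tests.
6. **`seaway.mapping`** — seasonal and season-averaged logistic probability
   surfaces, binary threshold maps, and loess-smoothed latitudinal profiles.

Rasters are read and written as ESRI ASCII grids (plain text) and
single-band GeoTIFF; models serialize to a diffable plain-text lambdas file.

## CLI

Each stage is a subcommand of `seaway` (see `--help` on each):

```sh
seaway synth  --config cfg.yaml --outdir run/synth --seed 1
seaway occur  --detections run/synth/detections.csv --sites run/synth/sites.csv \
              --latitude run/synth/latitude.asc --out run/presence.csv
seaway covars --bathy run/synth/bathymetry.asc --fields run/synth/stack \
              --attractors run/synth/attractors.yaml \
              --presences run/presence.csv --out run/covars
seaway fit    --samples run/covars/samples_summer.csv --reg 3 --out run/models
seaway predict --model run/models/model_summer.lambdas \
               --stack run/covars/stack --season summer --out run/surface.asc
seaway eval   --samples run/covars/samples_summer.csv --folds 10 --seed 1 \
              --out run/eval
seaway map    --models run/eval --stacks run/covars/stack \
              --latitude run/synth/latitude.asc --out run/maps
```

An example configuration is written by the CLI tests
(`tests/test_pipeline_cli.py`); all keys are optional and default to a
200 x 60 km shelf with two attractors.

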