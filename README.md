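# speclai

Characteristic-band selection and machine-learning regression for estimating
canopy leaf area index (LAI) from hyperspectral reflectance, plus a synthetic
field-campaign generator so the entire pipeline is testable and reproducible
without field data.

## What it does

- **Synthetic campaign** (`speclai.synthetic`): a replicated
  4-cultivar x 4-nitrogen plot design observed at three growth stages;
  log-normal LAI values peaking at booting (pooled mean ~5.4, SD ~1.7);
  fine-grid (1 nm) canopy reflectance from a two-flux Beer-Lambert
  soil/canopy mixture with nitrogen-dependent absorption wells (red valley
  near 674 nm), a logistic red edge (690-790 nm) and a NIR plateau.
- **Sensors & I/O** (`speclai.sensors`): 1-based band grids (the default
  imaging grid: 125 bands, 450 nm start, 4 nm sampling, 8 nm FWHM),
  Gaussian/boxcar spectral-response resampling, trimming to the reliable
  band range 3-96 (458-830 nm, 94 variables), pooled cross-sensor R², and
  CSV spectra tables with a JSON grid sidecar.
- **Preprocessing** (`speclai.preprocessing`): central-difference first
  derivative, band-wise Pearson correlation against LAI, and the
  correlation-threshold rule picking one peak band per contiguous
  high-correlation run.
- **Selection** (`speclai.selection`): successive projections (SPA) scored
  by MLR validation RMSE, competitive adaptive reweighted sampling (CARS)
  with the exponential decreasing retention schedule, adaptive reweighted
  sampling, and 10-fold RMSECV, plus the SPA-then-CARS chain. All return
  per-iteration diagnostic traces and serialize to JSON.
- **Models** (`speclai.models`): PLSR (CV-chosen components), RBF-kernel SVR
  (standardized bands, grid-searched C/gamma) and a self-contained
  second-order gradient-boosted tree regressor (`speclai.boost`) with the
  conventional seven-way hyperparameter grid. CV folds are keyed to sample
  ids, so fits are invariant to row permutation and duplication.
- **Evaluation** (`speclai.evaluation`): R² (squared Pearson), RMSE, RPD
  with its qualitative quality bands, the area-based calibration/validation
  split (areas 1 and 3 calibrate, area 2 validates) and the 15-row
  method x variable-set comparison table.
- **Pipeline & CLI** (`speclai.pipeline`, `speclai.cli`): end-to-end run
  with archived config, logs and artifacts, and a per-pixel LAI map over a
  synthetic reflectance cube.

## CLI

```sh
speclai simulate --n-plots 44 --seed 1 --out spectra.csv
speclai select spectra.csv --method CARS_SPA --seed 1
speclai fit spectra.csv --method PLSR --bands 3,15,40,80 --out model.json
speclai evaluate spectra.csv model.json
speclai compare --seed 1 --out run_dir        # full 15-model comparison
speclai map model.json --size 32 --out lai_raster.csv
```

`speclai compare` writes `comparison.csv`, `selections.json`, `scatter.csv`,
`best_model.json`, the archived `config.yaml`, and `run.log` into the output
directory; a fixed seed makes every artifact byte-reproducible.

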