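# petrad

A tested, reusable pipeline linking 3D PET radiomic texture features to the
tumor-to-normal brain uptake ratio (TNR):

* **Voxel model & I/O** (`petrad.image_model`) — NIfTI read/write of 3D SUV
  volumes, rectangular region extraction.
* **Discretization** (`petrad.discretize`) — equal-size (`es`) and
  equal-probability (`ep`) gray-level binning, default 128 levels.
* **Features** (`petrad.features`) — first-order statistics on the original
  values; 3D co-occurrence (GLCM) and run-length (GLRLM) statistics over 13
  directions at distance 1, mean-aggregated; geometric features including
  per-gray-level box-counting and correlation fractal dimensions.
* **TNR** (`petrad.tnr`) — SUVt by exhaustive hottest-1 cm³ window search,
  SUVn over a reference region, TNR = SUVt/SUVn.
* **Stability model** (`petrad.stability`) — Pearson pre-filter (p < 0.05),
  train-split standardization, log10 target, L1-regularized regression with
  seeded 5-fold CV, 300 random 70/30 splits, back-transformed MAE/RMSE/
  Spearman metrics, and cross-test predictor occurrence aggregation.
* **Synthetic cohorts** (`petrad.synthetic`) — PET phantoms with planted
  SUVt/SUVn/TNR ground truth and cohorts whose log10(TNR) follows a planted
  linear model, so the whole pipeline is testable without patient data.

Feature identifiers follow a fixed grammar, frozen in
`petrad.registry.feature_ids` (e.g. `Max_AD_md__orig`,
`Cluster_p_s_nd__ep_b128_d1_mean`, `fractal_bc_d_22__es_128`).

## CLI

```bash
petrad simulate --seed 0 --out cohort/                # phantoms + ground truth
petrad extract  --input cohort/ --out features.csv \
                --levels 128 --scheme both --tnr-out tnr.csv
petrad fit      --features features.csv --tnr tnr.csv \
                --out model/ --seed 0 --n-tests 300
petrad run-all  --out run/ --seed 0                   # all of the above
```

Every command writes a manifest (config, version, seed, input hashes) next
to its outputs; identical inputs and seeds give byte-identical tables.

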