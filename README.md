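# roiclass

Multi-site ROI-table harmonization and repeated nested-CV classification
benchmarking, with permutation-null significance testing and ROI importance
mapping. The package implements the full workflow for case–control studies
built on atlas-summarized brain measures (cortical thickness / surface area /
subcortical volume tables, or white-matter FA / RD tract tables), exercised
end-to-end on a synthetic multi-site cohort generator with known ground truth.

## What it does

1. **Schemas & cohorts** (`roiclass.schemas`, `roiclass.cohort`) — fixed
   feature schemas (152-feature structural, 41-feature diffusion), CSV/TSV
   cohort IO, complete-case filtering, binary group selection (pooled group
   sets supported).
2. **Synthetic cohorts** (`roiclass.synthetic`) — multi-site generator with
   additive/multiplicative site effects (normal / inverse-gamma), age/sex
   covariate effects, and a Cohen's-d group effect planted on a chosen ROI
   subset; fully reproducible from a seed, ground truth returned alongside.
3. **Harmonization** (`roiclass.harmonize`) — parametric empirical-Bayes
   location/scale (ComBat-style) site harmonization with configurable
   covariate design and covariate restoration.
4. **Pipeline** (`roiclass.pipeline`) — majority-class undersampling,
   per-feature min-max scaling, a linear SVC (C grid 0.1–2.0 step 0.05) and a
   two-hidden-layer dense softmax classifier (pure numpy, full-batch Adam,
   dropout + l2 on hidden layer 1, linear activations by default).
5. **Evaluation** (`roiclass.evaluate`) — repeated protocol: rebalance,
   stratified 80/20 split, 10-fold stratified grid search (scaler fit inside
   each training fold), best fold pipeline scored on the untouched test split;
   PPV/NPV/SEN/SPC/AUC/ACC per iteration.
6. **Inference** (`roiclass.inference`) — permutation-null runs (train/val
   labels permuted, grid search disabled, fixed winning hyperparameters),
   counting-rule p-values, and the frequency distribution comparison index
   (FDCI; 0.5 = equipoise) between two accuracy distributions.
7. **Importance** (`roiclass.importance`) — mean |SVC weight| and dense-net
   connection-weight backtracking relevances, aggregated over iterations and
   min-max normalized.
8. **CLI** (`roiclass.cli`) — `simulate`, `harmonize`, `evaluate`, `compare`,
   `importance`, `run-study`.

## CLI quick start

```bash
# synthetic two-site cohort with a planted effect on 8 ROIs
roiclass simulate --sites 2 --controls 60 --cases 60 --effect-size 1.5 \
    --affected 8 --site-shift-sd 1.0 --seed 1 --out scratch/demo

# harmonize across sites (age+sex in the design, not restored)
roiclass harmonize scratch/demo_cohort.csv --out scratch/demo_harmonized.csv \
    --model-out scratch/combat.json

# repeated nested-CV evaluation of the linear SVC
roiclass evaluate scratch/demo_harmonized.csv --model svc -R 100 --seed 1 \
    --out-prefix scratch/svc --save-models scratch/svc_models

# importance map from the saved per-iteration models
roiclass importance scratch/svc_models --out scratch/importance.csv

# or the whole study (both models, null runs, significance, FDCI) in one go
roiclass run-study scratch/demo_cohort.csv -R 50 --seed 1 --outdir scratch/study
```

`run-study` accepts a YAML config (see `roiclass.cli.RunConfig`) with CLI
overrides for the iteration count and master seed; every output embeds the
resolved configuration for auditability.

## Notes

- Harmonization is fit on the full dataset before splitting by default,
  matching the published workflow; `combat_within_train` in `RunConfig`
  switches to the leakage-free per-iteration refit.
- The dense classifier's full hyperparameter grid (~2.9M combinations) is
  searched by seeded random subsampling by default (`dlc_grid_k`);
  `--exhaustive` enumerates the complete grid.
- Test fixtures are generated programmatically; nothing binary ships with the
  repository.
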