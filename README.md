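# catena

Latent-variable modelling of catecholaminergic-nucleus integrity from
multimodal brainstem MRI, built around three pieces:

- **Peak-intensity-ratio extraction** — slice-wise
  `(max(ROI) − max(Ref)) / max(Ref)` contrast ratios per hemisphere from
  masked NIfTI volumes, with ventricle exclusion, FSE acquisition
  averaging, ±3 s.d. outlier screening and ×100 scaling.
- **A self-contained SEM engine** — declarative model specs over
  reticular (RAM) matrices, full-information maximum likelihood under
  missing data (pattern-grouped, analytic gradients), multi-group
  estimation with equality constraints, χ²/RMSEA/CFI fit indices,
  likelihood-ratio tests, the configural→weak→strong→strict measurement
  invariance ladder, and standardized solutions.
- **Study-model builders** — modality-specific and second-order
  multimodal integrity factor models, the correlated three-factor
  cognitive model (WM/EM/Gf, 10 tasks), unified neurocognitive
  correlation/regression variants (optionally with a higher-order MTL
  volume factor), longitudinal stability models, two-occasion latent
  change score models, and change→future-cognition prediction models
  with age.

A **synthetic-cohort generator** renders multimodal volumes (MT+, MT−,
FSE), masks, cognitive scores and regional volumes from a fully known
latent ground truth, so the whole pipeline is testable end to end
without any external data.

## CLI

```sh
# full pipeline: simulate -> extract -> fit -> report
catena all --outdir out --seed 0

# individual stages
catena simulate --out cohort --seed 3 --n-young 30 --n-old 30
catena extract --volumes cohort/volumes --masks cohort/masks --out ratios.csv
catena build --family neurocog --variant regression --out spec.json
catena fit --model spec.json --data wide.csv --out fit.json --seed 11
catena lrt --free free.json --nested nested.json
catena fixtures --size tiny --out fixtures
```

Exit codes: 0 success, 1 user error, 2 internal error. `--seed`
overrides any config seed; identical seeds reproduce all CSV/JSON
outputs byte for byte.

## Layout

```
src/catena/
  synthetic/    cohort generator (config, ground truth, rendering, missingness)
  extraction/   peak-ratio extraction, table cleaning, NIfTI I/O
  sem/          model spec, implied moments, FIML, fitting, inference
  models/       study-model builders and reported comparisons
  pipeline.py   stage orchestration and run manifest
  cli.py        click CLI (`catena`)
```
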