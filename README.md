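# methrel

Replicate-based reliability evaluation of DNA-methylation array preprocessing
pipelines and DNAm-based predictors.

## The problem

Epigenetic clocks, mortality scores, cell-fraction estimators and other
DNAm-based predictors are weighted linear combinations of CpG methylation
levels (beta values) read from Infinium-style two-channel arrays. Their
estimates inherit every technical artifact the raw intensities carry —
additive background, red/green dye imbalance, the compressed dynamic range of
Infinium type II probes, and chip/position/plate/well batch effects. Which
preprocessing strategy best removes this technical variation differs between
predictors, and a poorly chosen pipeline can *add* spurious variation.

Technical replicates — the same DNA assayed twice at separate occasions —
make the question measurable: a good pipeline yields predictor estimates that
agree within replicate pairs. `methrel` packages that evaluation logic for
methods researchers and pipeline developers:

- a **synthetic-data generator** producing Infinium-like intensity data with
  a known ground truth and independently switchable artifact classes
  (so every correction kernel can be validated against what was injected);
- a **composable preprocessing grid** — background correction (out-of-band or
  negative-control based), dye-bias correction (global channel rescaling or
  regression on paired internal controls), quantile normalization at three
  stratification levels, and probe-type calibration by regression on
  neighboring type I/II probe pairs;
- a **predictor engine** for user-supplied or synthetic coefficient tables,
  including the piecewise log-linear age calibration of first-generation
  clocks and non-negative least-squares cell-fraction deconvolution;
- **reliability statistics**: the six classical intraclass correlations with
  F tests and confidence intervals, batch-effect variance decomposition, and
  replicate-subsampling design curves;
- **downstream association analyses**: distribution summaries (mean, SD, CV),
  age-acceleration residuals, Cox proportional-hazards mortality association,
  and rank aggregation of pipelines across predictors.

## The statistics at the core

For n replicate pairs measured at k = 2 occasions, the two-way ANOVA mean
squares (MSR rows/subjects, MSC columns/occasions, MSE residual, MSW within)
give the ICC family; the single-measurement, absolute-agreement form used as
the headline consistency measure is

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

with the consistency form ICC(3,1) = (MSR − MSE)/(MSR + (k−1)·MSE) blind to a
constant occasion offset, one-way forms ICC(1,·) from MSB/MSW, and averaged
forms ICC(·,k). Confidence intervals use the standard F-distribution
constructions; the implementation is verified against an independent
sums-of-squares oracle to 1e-10.

A predictor is scored as `s = intercept + Σ_j w_j β_j`, optionally calibrated
to years through the inverse of F(age) = log(age+1) − log(adult_age+1) for
age ≤ adult_age, (age − adult_age)/(adult_age+1) above. Pipeline quality
propagates downstream: per-pipeline ICC is correlated (Spearman) with the
age correlation, hazard ratio and z-score the same pipeline produces in an
independent, non-replicated sample.

## Worked example

```python
import methrel as mr

cfg = mr.ExperimentConfig(
    seed=7, n_probes=1000, n_subjects=250, n_replicate_pairs=40,
    grid={"bg": ["none", "oob"], "dye": ["none", "relic"],
          "norm": ["none", "q1"], "probe": ["none", "rcp"]},
    predictors=[
        {"name": "SynthClock", "n_probes": 200, "target": "age", "transform": "horvath_age"},
        {"name": "AgingScore", "n_probes": 150, "target": "latent_score"},
        {"name": "Random", "n_probes": 80, "target": "random"},
    ],
)
bundle = mr.run_experiment(cfg)
print(bundle.ranking.summary.round(3))
print(bundle.ranking.median_rank.sort_values().head(3))
```

prints

```
            median_icc  min_icc  max_icc                          best_pipeline
predictor
AgingScore       0.944    0.814    0.954   bg=oob_dye=relic_norm=none_probe=rcp
Random           0.963    0.848    0.972  bg=none_dye=relic_norm=none_probe=rcp
SynthClock       0.870    0.665    0.896   bg=none_dye=relic_norm=q1_probe=none

pipeline
bg=oob_dye=relic_norm=none_probe=rcp     2.0
bg=none_dye=relic_norm=none_probe=rcp    3.0
bg=none_dye=relic_norm=q1_probe=rcp      4.0
```

Reading it: each row is one predictor's consistency profile across the
16-pipeline grid — its median/min/max replicate ICC(2,1) and the pipeline
that maximized it. The spread (e.g. 0.665–0.896 for the synthetic clock)
shows how much the analytical choice alone moves reliability. The second
table aggregates: pipelines are ranked within each predictor (1 = highest
ICC) and summarized by their median rank; dye-bias correction plus probe-type
calibration dominates here, while the raw pipeline ranks 16/16. The six ICC
types rank the predictor × pipeline cells near-identically (mean Spearman
rho 0.993 in this run, via `mr.compare_icc_types(bundle)`).

The same stages are exposed as a CLI for file-based work:

```bash
methrel simulate --config cfg.yaml --out data/
methrel preprocess --data data/ --manifest data/manifest.tsv --grid --out betas/
methrel predict --beta betas/beta_raw.tsv --models data/models --out est.tsv
methrel reliability --estimates est.tsv --sample-sheet data/sample_sheet.csv --out icc.tsv
methrel run --config cfg.yaml --out run1/
```

All inputs and outputs are plain text: beta/intensity matrices as TSV
(probes × arrays), sample sheets as CSV, predictor models as CSV with a
`# name=` / `# transform=` / `# intercept=` metadata header.

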