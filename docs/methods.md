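# Methods

This note records the models behind `methrel`, the defaults and why they were
chosen, and what the synthetic benchmark does and does not demonstrate.

## Synthetic cohort model

### Ground truth

Per-probe mean methylation is drawn from a three-class logit-normal mixture
(hypomethylated / hemimethylated / hypermethylated with probabilities
0.45/0.10/0.45 and logit means −2.5/0/+2.5, SD 0.5), reproducing the bimodal
beta-value distribution of blood methylomes. Subjects deviate from the probe
mean on the logit scale (SD 0.5). A configurable fraction of CpGs (default
10%) drifts linearly with age on the logit scale: probe j gains
`slope · w_j · (age − age_mean)` logits, with per-probe weights w_j ~ N(0,1)
and a default slope of 0.02 logits/year/unit-weight. The latent aging score
is `Σ_j w_j β_ij` over the aging CpGs; because the weights are drawn
independently of the slope, setting the slope to zero decouples the score
from age (a property the tests exercise). Probes joined by a neighbor-pair id
(the stand-ins for genomically adjacent Infinium type I/II pairs) are
assigned identical true methylation.

Ages are N(56.1, 12.4²) years truncated at 18, matching a middle-aged
population cohort. Mortality follows an exponential hazard
`h_i = b · exp(log_hr · z_i)` with z the standardized latent score,
administrative censoring at 10 years, and default log-HR 0.5 per SD. The
baseline hazard b is solved numerically so the expected event fraction equals
the configured rate (default 15%), so the realized event rate matches the
target within binomial error by construction.

### Intensity model

Each measurement is
`intensity = S_j · f · gain + background`, where S_j is a per-probe lognormal
total signal (median 5000, log-SD 0.4), f is the allele fraction (β′ for the
methylated read, 1−β′ for the unmethylated read), and `gain` multiplies
per-array log-scale effects for the measurement's color channel:

- **dye bias** — a per-array red-channel factor exp(N(0, dye_bias_sd)),
  default SD 0.10;
- **batch effects** — independent log-scale effects per level of chip,
  position, plate and well, drawn **per channel** (default SDs 0.075, 0.045,
  0.06, 0.045). Channel-specific draws are essential: a batch effect common
  to both channels cancels almost exactly in the beta ratio and would leave
  predictor estimates untouched. The default magnitudes were sized so the
  four factors jointly explain ≈5% of predictor variance at the default
  cohort scale, the regime reported for well-run EPIC studies;
- **occasion shift** — one common log-scale factor per array (SD 0.05).

Type II probes report `β′ = 0.5 + c_a (β − 0.5)` with a per-array compression
factor `c_a = c + N(0, c_sd)` (defaults c = 0.85, c_sd = 0.04, clipped to
[0.05, 1]). The per-array component matters: a strictly constant compression
rescales a type-II probe's signal and noise identically and leaves replicate
agreement invariant, whereas real probe-type bias severity varies with
scanner and chemistry conditions from array to array — which is precisely the
variation a per-array calibration can remove.

Background is additive truncated-normal (non-negative) around a per-array,
per-channel level `bg_mean · exp(N(0, bg_array_sd))` (defaults: mean 300,
draw SD 50, array-level SD 0.10). Out-of-band (OOB) draws for type-I probes
and negative-control probes sample this same law, which makes both background
estimators unbiased for the injected level — OOB/negative-control correction
is identifiable by design. Same-target control pairs carry one fixed
lognormal signal observed in both channels, so the per-array channel
imbalance is identifiable from them.

Infinium conventions followed: type I probes read both alleles in one
assigned channel (their unused channel provides the OOB draw); type II probes
read methylated in green, unmethylated in red.

Replicate pairs share true betas but receive fully independent technical
draws, and by default the second occasion starts on a fresh chip so the two
arrays of a pair sit on different chips (configurable via
`replicates_share_chip`; the real layout of replicate batches is generally
not published, so this is a modeling choice flagged in the config).

### What the generator does not emulate

No genome coordinates, SNP-affected or cross-reactive probes, copy-number
artifacts, cell-composition heterogeneity, intensity-dependent (non-linear)
dye bias, or spatial within-chip gradients. Passing tests therefore show
that each kernel removes the artifact class it targets *under this model*,
not that any pipeline is optimal for a particular real dataset — the
framework's point is exactly that such claims need study-specific replicates.

## Preprocessing kernels

- **Detection p-values**: one-sided upper-tail probability of a probe's total
  (meth+unmeth) intensity under a normal approximation of the per-array,
  per-channel negative-control law; a type-I null total sums two draws in one
  channel, a type-II null one draw per channel.
- **Sample QC**: exclude arrays with >5% of CpGs at detection p > 0.05, or
  with log2 median (un)methylated intensity below median − 3·MAD
  (normal-consistent) of the array medians.
- **Background** (`oob`/`neg`): subtract the per-array, per-channel mean of
  the designated background source, flooring at 1 intensity unit.
- **Dye** (`mean`/`relic`): `mean` rescales the red channel so mean red
  control totals equal mean green; `relic` regresses log green-control on log
  red-control totals across the control pairs per array and maps every
  red-channel measurement through the fitted line. For a purely
  multiplicative bias both reduce to the same scale factor.
- **Quantile normalization** (`q1`/`q2`/`q3`): reference distribution is the
  mean of sorted columns, ties resolved by average rank; q1 stratifies by
  {meth, unmeth} × {type I, type II}, q2 by {meth, unmeth}, q3 pools
  everything. These stratification semantics are this package's definitions.
- **Beta**: β = meth/(meth+unmeth+offset), offset 100 by platform-standard
  convention (0/0 → 0).
- **Probe-type calibration** (`rcp`): per array, a robust line (Tukey
  bisquare IRLS, tolerance 1e-8, max 50 iterations, with an exact OLS
  shortcut when the fit is perfect) of type-I beta on type-II beta over the
  neighbor pairs, applied to all type-II probes and clipped to [0, 1]. The
  regression scale is a parameter: the default `"beta"` exactly inverts the
  generator's beta-linear compression; `"logit"` (clipping betas to
  [1e-6, 1−1e-6] first) is provided for users whose bias model is
  logit-linear.

Pipelines run bg → dye → norm on intensities, then compute betas, then the
probe-level correction. The grid enumerator forms the Cartesian product of
axis options plus the all-`none` ("raw") spec; the default experiment grid is
24 pipelines and is configuration-expandable — the report schema does not
depend on grid size.

## Predictor engine

Linear scoring with two missing-data policies: `error` (list the absent
probes) and `mean_impute` (default, mirroring the field's preference for
imputation over probe filtering): NaN cells of a present probe are filled
with that probe's across-array mean; a probe absent from the matrix entirely
is filled per array with the mean beta of the model's present probes, both
logged. The age calibration is the piecewise log-linear form anchored at
adult age 20 used by first-generation clocks; its exact forward/inverse pair
is implemented and round-trip tested. Whether that form applies to any
*particular* published clock should be checked against that clock's
documentation — the CSV model format carries `transform` and `adult_age`
fields so other conventions can be expressed.

Cell-fraction deconvolution solves non-negative least squares per array
(active-set NNLS; an SLSQP refinement with bounds [0,1] and Σf ≤ 1 only when
the simplex constraint binds, so noise-free mixtures are recovered at machine
precision), with optional renormalization to Σf = 1 and a condition-number
warning for nearly collinear references. Two-level composites (a parent
score over sub-predictor outputs) are supported; deeper nesting is not.

## Reliability statistics

The six ICCs follow the classical two-way decomposition; estimates are
reported as computed (negative values flagged, not floored). The F test is
MSR/MSE with (n−1, (n−1)(k−1)) degrees of freedom; the one-way F (MSB/MSW) is
also reported. Confidence intervals use the standard F constructions,
including the Satterthwaite-style degrees of freedom for the
absolute-agreement form; the implementation agrees with an independent
reference implementation to 1e-10 (estimates) and 0.01 (interval endpoints)
in the test suite. Zero total variance raises a degenerate-data error rather
than returning a value. Pairs with a missing member are dropped listwise and
logged.

The direct replicate-table simulator draws `y_ij = u_i + c_ij + e_ij` with
the occasion effect c independent **per measurement**: each array of a pair
is processed at its own occasion, so occasion draws do not repeat across
pairs. Under this model the population single-measurement agreement ICC is
σ²_u/(σ²_u+σ²_c+σ²_e) and the estimator concentrates at rate 1/√n, which the
parameter-recovery test verifies at (9, 0.5, 0.5)/n=500.

Batch variance decomposition reports the raw OLS coefficient of
determination of the estimate on jointly dummy-encoded factors (its null
expectation ≈ p/(n−1) for p dummies is part of the reported quantity, and the
null-calibration test asserts exactly that), per-factor *marginal* R² (a
deliberate choice — the factors are not orthogonal, so sequential R² would
depend on ordering), and residualized estimates. `regress_out_batch` returns
residual + grand mean so downstream ICC remains well-scaled.

Subsampling analysis draws pair subsets without replacement (shared across
all predictor × pipeline cells), recomputes the chosen ICC per cell, and
reports the mean Spearman correlation with the full-sample ICC vector per
subset size.

## Association statistics

Distribution summaries use the n−1 SD; CV is undefined (NaN) at zero mean.
Age acceleration is the OLS residual of the estimate on age. Cox models are
fitted by partial likelihood with Efron tie handling (via lifelines),
adjusted for supplied covariates; hazard ratios are per unit of the raw
predictor by default with a per-SD standardization flag, since unit
conventions differ between studies. Spearman correlation uses average ranks,
a t approximation for n ≥ 10 and exact permutation enumeration below that;
zero rank variance returns an undefined marker. Pipeline ranking assigns
average ranks on ties and ranks degenerate (zero-variance) cells last so
pipeline counts stay comparable across predictors.

## Numerical and design choices

- One seed per experiment; per-stage sub-seeds derived via `SeedSequence`,
  so runs are bit-reproducible and stages are independently perturbable.
- Background floor 1.0 intensity unit; logit clipping at 1e-6; beta clipping
  events counted and logged.
- QC exclusions that orphan a replicate pair demote the surviving array to
  an unpaired sample rather than invalidating the dataset.
- Rank-correlation diagnostics are skipped (with a log entry) below 4
  pipelines, where the statistic is undefined.
- Degenerate inputs raise typed errors (`DegenerateDataError`,
  `DesignError`, `CapabilityError`, ...) rather than returning silent NaNs,
  except where an "undefined marker" is the documented output (CV, Spearman
  under zero rank variance).

## Benchmark problem sizes

The shipped configurations are desk-scale by design: manifests of 300–2000
probes (the framework is size-agnostic; nothing in the code depends on probe
count beyond memory), cohorts of tens to hundreds of subjects, grids of
12–24 pipelines, artifact-recovery studies over 20 seeds, and Cox
calibration at n = 400–1500 with ~15% events. These sizes give the Monte
Carlo studies enough resolution for the tolerances asserted in the tests
while keeping a full run in the minutes range.

## Known limitations

- The preprocessing grid reproduces the *structure* of large multi-package
  pipeline comparisons (background × dye × normalization × probe-type), not
  any specific package's internals; results about a named published pipeline
  cannot be read off from it.
- ICC formulas are implemented for general k but tested at k = 2 replicates.
- The Cox stage fits one predictor at a time; no competing risks, no
  multi-predictor joint models.
- Published predictor coefficient tables are not bundled; the model-CSV
  format accepts them if the user supplies them, and synthetic models are
  the test surface.
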