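# gada-discrim

A tested, reusable implementation of a two-step procedure for deriving and
applying a five-variable linear discriminant tool that separates adult-onset
GADA-positive autoimmune diabetes from type 2 diabetes using routine
clinical measurements (age at onset, BMI, triglycerides, HDL-C, HbA1c).

Because no patient-level data is distributed, the package ships a synthetic
cohort generator whose per-group marginal statistics emulate the published
summary table, so every pipeline stage is exercisable end to end.

## What it does

1. **Between-group screening** — pooled-variance Student's t for continuous
   variables, Pearson chi-square (no continuity correction) and two-sided
   Fisher exact tests for categorical ones, and a Lilliefors-corrected
   Kolmogorov–Smirnov normality screen.
2. **ROC cutoffs** — empirical ROC per significant laboratory variable with
   the closest-to-corner criterion
   `sqrt((1 - sensitivity)^2 + (1 - specificity)^2)`; rank-based AUC with a
   Hanley–McNeil 95% CI.
3. **Discriminant analysis** — two-group canonical LDA (closed form via the
   pooled within-group covariance): standardized coefficients,
   structure-matrix loadings, eigenvalue / Wilks' lambda / canonical
   correlation, per-group Fisher classification functions. Variables with
   |loading| ≤ 0.3 are dropped and the model is refit on the survivors.
4. **Scoring and evaluation** — indicator encoding (age and BMI bins,
   cutoff exceedances), Fisher-function classification, confusion-matrix
   accuracy / sensitivity / specificity.

The published coefficients and cutoffs ship as a packaged artifact
(`gada_discrim/data/published_model.json`) usable without refitting.

## CLI

```sh
# synthesize a cohort at the published group sizes (152 / 358)
gada-discrim simulate --seed 7 --out cohort.csv

# run the full derivation pipeline; writes four report tables + model.json
gada-discrim derive cohort.csv --out-dir derived/

# score a cohort with the packaged published model (or --model derived/model.json)
gada-discrim score cohort.csv --published --out predictions.csv

# render a model artifact
gada-discrim report --published
```

Useful flags: `--n-gada/--n-t2dm`, `--mode MOMENT_MATCH|BIN_CALIBRATED`,
`--config sim.toml` (simulate); `--alpha`, `--loading-threshold`,
`--priors equal|proportional`, `--no-select` (derive).

## Library

```python
import gada_discrim as gd

cohort = gd.generate_cohort(gd.default_config(seed=1))
rows = gd.compare_table(cohort)                      # step-1 statistics
cuts = gd.cutoffs_for_variables(cohort, ["tg", "hba1c", "hdl"])
iv = gd.encode_indicators(cohort.records[0])
score = gd.fisher_classify(gd.load_published_model().fisher, iv)
```

## Conventions worth knowing

- Bins are half-open, left-closed: age [20,30), [30,50), [50,∞); BMI
  (0,23), [23,25), [25,∞). Cutoff indicators use ≥ (boundary counts as
  exceeding). The source tables are ambiguous about boundary assignment;
  this is a documented choice.
- Priors default to equal (0.5/0.5); group-proportional priors only shift
  the Fisher constants by `ln(prior)`.
- Classification ties go to the T2DM (reference) group.
- The simulator's latent copula correlations are assumptions (the source
  reports only marginals) and are fully user-overridable.
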