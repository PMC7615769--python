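# doubleburden

Bayesian hierarchical meta-regression for estimating national trends in the
prevalence of underweight/thinness ("low") and obesity from heterogeneous
study-level prevalence data, together with all draw-level derived quantities:
double burden (combined prevalence), obesity share, posterior probabilities of
change and dominance, age-standardisation, persons affected, cross-country
correlations, crossover years, and country classification with
threshold-based counting rules.

The package is exercised end-to-end on synthetic study databases that have
exactly the statistical structure the model assumes (hierarchical linear +
second-order random-walk time trends, hierarchical cubic-spline age patterns,
coverage-level offsets, urbanisation effects, study-level random effects, and
binomial sampling noise), so every stage is testable without any download.

## Modules

| Module | Role |
| --- | --- |
| `doubleburden.study_db` | Domain types, CSV readers/writers, validation, logit/delta-method transform |
| `doubleburden.synthetic_cohort` | Latent surface generator, survey-design simulator, named fixture scenarios |
| `doubleburden.hier_model` | Model spec/context, MH-within-Gibbs sampler, prediction, convergence diagnostics |
| `doubleburden.posterior_quantities` | All derived quantities, computed strictly at posterior-draw level |
| `doubleburden.report` / `doubleburden.pipeline` / `doubleburden.cli` | Classification rules, counts with rounded percents, end-to-end pipeline and CLI |

## CLI

```sh
dbm simulate --scenario recovery --seed 1 --out data/     # synthetic file set
dbm fit --studies data/studies.csv --hierarchy data/hierarchy.csv \
        --spec spec.yaml --out fit/                       # draws + diagnostics
dbm summarise --draws fit/ --age-standard data/age_standard.csv \
        --population data/population.csv --out summary/   # tidy estimate CSVs
dbm all --config config.yaml                              # full pipeline
```

A minimal pipeline config:

```yaml
scenario: smoke        # or inputs: {studies: ..., hierarchy: ..., age_standard: ...}
seed: 1
out_dir: out/
model:
  mcmc: {iterations: 2000, chains: 4, thin: 5, seed: 1}
```

`dbm all` emits `estimates.csv`, `probabilities.csv`, `correlations.csv`,
`classifications.csv`, `diagnostics.csv`, `report.json` and a human-readable
`report.md`; the exit code is 0 iff convergence diagnostics are clean.
Re-running an identical config reproduces the outputs byte-identically.

## Model summary

Observed prevalences are logit-transformed with a continuity-corrected
delta-method sampling variance. Per category and sex, the mean of an
observation is a country-level logit prevalence surface — global, regional
and country intercepts and slopes, constrained RW2 non-linear trends at each
level, and a hierarchical cubic B-spline age curve — plus subnational or
community offsets, an urbanisation term, and a study-level random effect
whose variance depends on the coverage class. Fixed effects get Normal(0, 1)
priors; all SDs get half-Normal(1) priors. Sampling is MH-within-Gibbs:
conjugate normal block updates for all linear effects and adaptive log-scale
random-walk Metropolis (target acceptance 0.44) for the variance parameters.
National predictions exclude offsets and study effects. All derived
quantities are functions of the posterior draws; summaries are posterior
means with 2.5th–97.5th percentile credible intervals.
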