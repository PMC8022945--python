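# zapforest

Zero-altered (hurdle) Poisson random forests for genomic prediction of count
traits with excess zeros.

Count traits in plant breeding (disease severity scores, seed counts, ...)
are often zero-inflated, which breaks both least-squares random forests and
plain Poisson regression. This package implements a two-part random forest:

1. **Zero part** — a binary forest (Gini splitting) fit to the indicator
   `I(y == 0)`, producing a per-observation zero probability `theta`.
2. **Truncated part** — a forest fit to the positive counts only, whose
   splitting criterion is the zero-truncated Poisson log-likelihood with
   each candidate child evaluated at its own rate MLE (the implicit solution
   of `mean = mu / (1 - exp(-mu))`), producing a positive rate `mu`.

Two prediction rules combine the parts:

- `ZAP_RF` (expected value): `(1 - theta) * mu / (1 - exp(-mu))`;
- `ZAPC_RF` (classify-then-count): `0` when `theta > 0.5`, else `mu`.

Also included: the comparison baselines (conventional least-squares random
forest, ridge regression, ridge-penalized Poisson regression), the three
evaluation metrics (Spearman correlation, MAAPE, MAE), a nested
cross-validation benchmark (outer 5-fold; inner 5-fold grid tuning for
forests, inner 10-fold penalty tuning for ridge models), permutation
variable importance with separate tables for the two model parts, and a
synthetic genotype/phenotype simulator with binary (0/1) markers,
environment replicates and marker-driven hurdle parameters.

## CLI

```bash
# simulate a dataset shaped like the 115-line / 3-environment wheat data
zapforest simulate --preset dataset1_like --p 200 --seed 1 --out data/sim

# fit a hurdle forest and predict
zapforest fit --phenotype data/sim/phenotype.csv --genotype data/sim/genotype.csv \
    --ntree 300 --mtry 50 --nodesize 5 --out model.json
zapforest predict --model model.json --phenotype data/sim/phenotype.csv \
    --genotype data/sim/genotype.csv --rule mean --out predictions.csv

# nested-CV benchmark of several models (per-environment + pooled metrics)
zapforest cv --phenotype data/sim/phenotype.csv --genotype data/sim/genotype.csv \
    --models RR,GPR,RF,ZAP_RF,ZAPC_RF --seed 1 --out results/cv

# permutation variable importance (two tables: zero part, truncated part)
zapforest vim --phenotype data/sim/phenotype.csv --genotype data/sim/genotype.csv \
    --ntree 300 --out results/vim --plot
```

Input formats: a long phenotype CSV (`line,environment,count` — or a named
trait column selected with `--trait`) and a wide genotype CSV (first column
the line ID, remaining columns 0/1 marker codes). `zapforest convert-rdata`
dumps the contents of an `.RData` deposit to CSVs via `Rscript` so real
datasets can be brought into this layout.

With `--ge`, the design matrix additionally carries genotype-by-environment
interaction columns (line-within-environment indicators labeled
`Z.<line>.<env>`; marker-by-environment products are available through the
API's `ge_mode="product"`).

## Package layout

| module | contents |
| --- | --- |
| `zapforest.distributions` | ZTP/ZAP pmf, moments, log-likelihood, rate MLE, hurdle sampler |
| `zapforest.tree` | binary trees with least-squares / Gini / ZTP-likelihood splitting |
| `zapforest.forest` | bagged ensembles, prediction, JSON serialization |
| `zapforest.zap` | the two-part hurdle forest and both prediction rules |
| `zapforest.ridge` | ridge and Poisson-ridge baselines, CV penalty selection |
| `zapforest.metrics` | Spearman / MAAPE / MAE and fold mean ± SE summaries |
| `zapforest.pipeline` | folds, grid tuning, nested-CV benchmark, permutation VIM |
| `zapforest.data` | simulators, presets, design-matrix builder, CSV/RData IO |
| `zapforest.cli` | the `zapforest` command group |
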