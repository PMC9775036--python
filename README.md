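# dfsc — semi-supervised deep survival forest cascades

`dfsc` builds prognostic models from high-dimensional gene expression
(p ≫ n) with right-censored survival outcomes — the setting of TCGA-style
tumor cohorts, where a few hundred patients carry ~20,000 measured genes and
many samples lack usable follow-up. It is aimed at computational biologists
and biostatisticians who want a nonlinear, censoring-aware alternative to
penalized Cox regression that can also exploit unlabeled samples, together
with a robust gene-ranking step and honest evaluation metrics.

## The model

The hazard follows a proportional-hazards form

    h(t | x) = h0(t) · exp(η(x)),

where η(x) is produced not by a linear predictor but by a **deep survival
forest**: a cascade of levels, each holding an even mix of random survival
forests and completely-random survival forests (uniformly random split
feature and threshold, Nelson–Aalen leaves). Every forest emits an ensemble
log-risk feature per sample — computed **out of fold**, so no level ever sees
its own memorized outcomes — and level ℓ+1 trains on the original genes
concatenated with level-ℓ's forest outputs. An elastic-net-penalized Cox
model on the augmented features links each level to the partial likelihood

    ℓ(b) = ∏_j [ exp(η_j) / Σ_{i ∈ R_j} exp(η_i) ]^{σ_j},

supplies η, and scores the level on a held-out validation split; the cascade
grows until validation concordance stops improving. A Breslow estimator of
the cumulative baseline hazard H0 turns η into survival curves
S(t|x) = exp(−H0(t)·e^η).

**Semi-supervised learning.** A cascade fitted on labeled rows acts as a
teacher: for each unlabeled sample it imputes a median survival time and a
temperature-softened distribution over discrete risk bins,
P(y|x) = exp(f(x)[y]/τ) / Σ_y' exp(f(x)[y']/τ). Confident pseudo-labels join
the training data of a student cascade; rounds of teacher → student proceed
while concordance on an outer labeled validation split (held out from every
candidate) improves, with the distillation cross-entropy −Σ P_T log P_S
tracked as a convergence diagnostic. The best round wins; if none beats the
supervised baseline, the plain supervised fit is returned.

**Gene ranking.** Stable LASSO: B subsamples of half the cohort, an
L1-penalized Cox path on each; a gene's *stability score* is the fraction of
subsamples that select it at any grid penalty, reported with per-gene
univariate Cox Wald p-values (Tables of `gene_symbol / stable_score /
p_value`).

**Evaluation.** Harrell's concordance index, the IPCW (inverse probability
of censoring weighted) Brier score and its trapezoid-integrated summary, and
an event-stratified k-fold cross-validation harness with paired model
comparison (built-in baselines: L1 Cox, single random survival forest).

Because the original tumor cohorts require controlled downloads, the package
ships a generator of synthetic cohorts with known ground truth —
block-correlated expression, a sparse set of truly prognostic genes,
exponential proportional-hazards event times, calibrated censoring, and
labeled/unlabeled/test partitions shaped like the four emulated cohorts
(BRCA, CESC, COAD, PAAD) — so every claim is testable by parameter recovery.

## Worked example

```python
from dfsc import (CascadeConfig, GeneratorConfig, StabilityConfig,
                  concordance_index, fit_cascade, generate, stability_select)
from dfsc.synthetic_data import split_by_partition

cfg = GeneratorConfig(random_seed=7)          # n=300 samples, p=1000 genes
data, truth = generate(cfg)
labeled, _, test = split_by_partition(data, truth)

model = fit_cascade(labeled, CascadeConfig(n_trees_per_forest=50, max_levels=3,
                                           random_seed=7))
risk = model.predict_risk(test)
print(f"levels retained: {len(model.levels)}")
print(f"validation C-index: {model.best_validation_cindex:.3f}")
print(f"test C-index: {concordance_index(test.time, test.event, risk):.3f}")

report = stability_select(data.labeled(), StabilityConfig(random_seed=7))
for row in report.table.head(5).itertuples(index=False):
    hit = "  <- truly prognostic" if row.gene_symbol in truth.causal_genes else ""
    print(f"{row.gene_symbol}  score={row.stable_score:.2f}  p={row.p_value:.1e}{hit}")
```

prints

```
levels retained: 2
validation C-index: 0.770
test C-index: 0.804
G00940  score=1.00  p=2.8e-11  <- truly prognostic
G00390  score=1.00  p=1.8e-09  <- truly prognostic
G00050  score=1.00  p=6.9e-08  <- truly prognostic
G00010  score=1.00  p=1.2e-07  <- truly prognostic
G00500  score=1.00  p=6.7e-07  <- truly prognostic
```

A test concordance of 0.80 means that for 80% of comparable patient pairs
the model assigns the higher risk to the patient who dies earlier (0.5 is
chance; the generating-truth oracle reaches ≈0.9 on this cohort). All five
top-ranked genes are among the ten truly prognostic ones planted by the
generator, each selected in every LASSO subsample (score 1.00).

The same workflow is available from the shell:

```
dfsc simulate --preset PAAD --scale 0.5 --seed 1 --out-dir sim/
dfsc fit --expr sim/expr.tsv --clinical sim/clinical.tsv --unlabeled-ok \
         --out model.joblib --seed 0
dfsc select-genes --expr sim/expr.tsv --clinical sim/clinical.tsv \
         --top-k 20 --out genes.tsv
dfsc evaluate --expr sim/expr.tsv --clinical sim/clinical.tsv \
         --models lasso-cox,rsf --folds 5 --seed 7 --out report.tsv
```

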