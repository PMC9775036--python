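# Methods

## Model

`dfsc` fits right-censored survival outcomes under proportional hazards,
h(t|x) = h0(t)·exp(η(x)), with the log-risk η produced by a cascade of
survival-forest ensembles. The assumptions inherited from this form are the
usual Cox ones: non-informative right censoring, hazards proportional over
time, and outcomes independent across samples given x. Ties in event times
are handled with the Breslow convention throughout (partial likelihood and
baseline-hazard estimator agree); Efron/exact corrections, time-varying
covariates, competing risks and left truncation are out of scope. The risk
set at a subject's event time includes the subject itself
(time_i ≥ time_j), and the partial likelihood is computed in the log domain
with running log-sum-exp so that forest-scale risk scores cannot overflow.

### Cascade construction

Each level holds `n_forests_per_level` forests, split evenly between
standard random survival forests (log-rank splits, √p feature subsampling)
and completely-random survival forests — trees whose split feature and
threshold are drawn uniformly at random (realized as extremely-randomized
survival trees restricted to one candidate feature per split), with
Nelson–Aalen estimates in the leaves. The two variants exist to keep the
ensemble diverse.

Each forest contributes one prediction feature per sample: log1p of its
ensemble risk score (survival forests have no class-probability vector, so
the ensemble log-risk is the survival analogue of the class-vector currency
that deep-forest cascades usually pass forward; `n_outputs_per_forest > 1`
appends survival probabilities at quantile horizons). Features a forest
feeds forward for its own training rows are computed **out of fold** via
internal 3-fold cross-fitting; new rows (validation, test) are scored by
averaging the three fold models. This is the cascade's central engineering
risk: a property test verifies that an intentional in-fold variant inflates
validation concordance to ≈0.88 on pure-noise data while the out-of-fold
path stays at 0.50 ± 0.05.

Level ℓ+1 trains on the original gene matrix concatenated with all level-ℓ
forest outputs (so with p genes and 4 forests the augmented dimension is
p + 4). An elastic-net-penalized Cox model on the augmented features yields
the level's η. Its penalty is chosen on a 5-point log-spaced grid anchored
at the data-driven maximal penalty, scored by 3-fold cross-validated log
partial likelihood; alphas whose full fit has empty support are barred from
the choice unless the whole path is empty, because a constant predictor
cannot rank. Growth is steered by an event-stratified validation split
(`validation_fraction`, default 0.2): a new level is retained only when it
improves validation concordance by more than `min_improvement` (default
0.005), and growth stops after `patience` levels without such improvement
or at `max_levels`. The retained model's final validation concordance
therefore equals the running maximum over grown levels up to that margin;
the margin exists because with a small validation set a noise-level gain
would otherwise flip a coin on whether depth helps or hurts. The final η on
the training data feeds the Breslow cumulative baseline hazard, giving
survival curves S(t|x) = exp(−H0(t)e^η).

Defaults: 4 forests/level, 100 trees/forest, `max_levels` 5, patience 1,
l1_ratio 0.5, validation fraction 0.2. These follow deep-forest convention
at desk-compute scale; every one is exposed in `CascadeConfig`.

### Semi-supervised driver

The teacher–student loop in `fit_dfsc`:

1. Hold out an outer labeled validation split (fraction
   `validation_fraction`, event-stratified) from **everything** below.
2. Fit a teacher cascade on the remaining labeled rows (this is also the
   round-0 candidate).
3. Pseudo-label the unlabeled pool: the imputed outcome is the smallest
   baseline event time where the teacher's survival curve drops to 0.5
   (the last event time if it never does), treated as an event by default
   (`pseudo_as_censored` flips this); the soft label is a temperature
   softmax over `n_risk_bins` quantile bins of the teacher's training
   log-risk, with bin scores −|η − center| measured in quarter-bin-spacing
   units so that at the default τ = 2 a sample at a bin center is
   confidently assigned (~0.87 max probability with 4 bins) and a sample on
   a bin boundary is not (~0.45). Only pseudo-labels with confidence ≥
   `confidence_threshold` (default 0.7) are used.
4. Fit a student on labeled-core + accepted pseudo rows (pseudo rows are
   barred from every internal validation split); evaluate it on the outer
   split; track the distillation cross-entropy −Σ P_T log P_S on the
   pseudo-labeled pool as a convergence diagnostic. The student becomes the
   next teacher; rounds stop at `max_rounds` (default 3) or when the outer
   concordance fails to improve by `min_improvement` (default 0.02).
5. If a pseudo-labeled round won, refit on **all** labeled rows plus that
   round's pseudo-labels (select-then-refit); otherwise return the plain
   supervised cascade on all labeled rows — which makes the degenerate
   cases (empty pool, unreachable confidence) bit-identical to
   `fit_cascade`.

The outer split exists because a teacher trained on the rows later used for
round selection launders its memorization of those outcomes into the
pseudo-labels and flatters every student; holding the split out of all
candidates makes the selection unbiased. The loop's "convergence" is
operationalized as this validation early stopping — the only measurable
criterion available.

As printed, a distillation objective of the form Σ P_T log P_S would be
unbounded below under minimization; the implemented loss is the standard
cross-entropy −Σ P_T log P_S, which by Gibbs' inequality is minimized in
the student exactly at P_S = P_T.

### Stability selection

`stability_select` draws B = 100 half-subsamples without replacement,
fits an L1 Cox path on a 10-point log-spaced penalty grid (anchored at the
data-driven maximal penalty, down to a 0.1 ratio) on each, and scores every
gene by the fraction of subsamples in which it receives a nonzero
coefficient at any grid penalty. Zero-variance genes score 0 and are
flagged. Significance is deliberately a separate column: per-gene
univariate Cox Wald p-values on the full data, raw by default with an
optional Benjamini–Hochberg adjustment, keeping multiplicity handling
explicit. Cohorts beyond 5000 genes are pre-screened to the 5000 most
variable before the subsampled fits (flag-disable-able). Subsamples with
fewer than two events are redrawn.

### Evaluation

Harrell's concordance counts a pair (i, j) as comparable iff
time_i < time_j and subject i had the event; concordant when the earlier
event has the higher risk; tied risks count half. (The IPCW variant of the
C-index is a non-goal.) The Brier score at horizon t weights events before
t by 1/G(T⁻) and subjects at risk past t by 1/G(t), with G the Kaplan–Meier
estimate of the censoring distribution; with no censoring it reduces
exactly to the mean squared error against survival status. The integrated
Brier score is the trapezoid average over a grid spanning the 10%–80%
quantiles of observed event times, normalized by the grid span — one
scalar per model, comparable across methods. Cross-validation folds are
stratified by event indicator because small event counts make unstratified
folds degenerate; `compare_models` reuses identical folds across model
specs so comparisons are paired.

## Synthetic cohorts

The generator emulates what matters statistically about genome-wide tumor
cohorts: p ≫ n, co-expression (consecutive gene blocks of size 10 with
exchangeable correlation 0.4), a sparse prognostic signal (10 causal genes
with |β| = 1, placed in distinct blocks, random signs), proportional-hazards
event times (exponential baseline; a Weibull shape is exposed but does not
affect rank-based metrics), right censoring with the censoring rate solved
numerically to hit a 30% target, and labeled/unlabeled/test partitions.
Presets reproduce the sample counts of four emulated cohorts
(BRCA 248/245/120, CESC 120/110/60, COAD 110/85/60, PAAD 65/61/50), with
gene counts capped at 2000 for desk runs. The default condition is n = 300,
p = 1000.

What it does **not** emulate: RNA-seq count noise (negative binomial),
batch effects, pathway-structured effects, informative censoring, or
nonlinear/non-proportional hazards. Passing tests on this generator
therefore show correct mechanics and honest calibration under a linear
proportional-hazards world, not performance on real transcriptomes. Two
consequences are worth naming. First, because the generating signal is
linear, the elastic-net Cox link captures most of it and deeper cascade
levels are rarely retained — the cascade-vs-first-level comparison lands at
parity rather than showing the gains nonlinear data could. Second,
pseudo-labels cannot add information the teacher does not have, so the
semi-supervised gain is small; it is positive where labels are scarcest
(the 65-labeled cohort shape) and indistinguishable from zero at n = 300,
with the selection mechanism bounding the downside in all conditions
measured.

## Numerical choices and degenerate inputs

- Partial likelihood and softmax computations are shift-invariant and use
  log-sum-exp / max-subtraction.
- 0·log 0 ≡ 0 in the distillation cross-entropy; student mass absent where
  the teacher has mass yields +inf.
- Constant genes: correlation reported as 0 with a flag; stability score 0.
- All-censored data: partial likelihood returns 0 with a warning (empty
  product); the Breslow estimator and cascade fitting refuse to run.
- Cascade preconditions: ≥ 20 labeled samples with ≥ 5 events.
- Tiny cross-validation folds without comparable pairs report NaN
  concordance rather than failing the whole harness.
- Reproducibility: per-level seeds are spawned from the config seed, so a
  deeper `max_levels` budget leaves earlier levels bit-identical, and every
  fit is deterministic under a fixed seed.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the cascade at a documented
desk scale — 50 trees per forest, two or three levels, two teacher–student
rounds — on the generator's default conditions (n = 300, p = 500–1000) and
the PAAD-shaped preset; stability selection uses B = 100 subsamples at
p = 500. These sizes keep full runs in the minutes range on a single CPU
while preserving the p ≫ n regime; the package defaults (100 trees, up to
5 levels) are what an analysis of a real cohort would start from.

## Known limitations

- The distillation loss is a diagnostic, not an optimized objective: the
  student minimizes the Cox partial likelihood on pseudo-labeled rows
  rather than the cross-entropy directly, which is the natural fit for
  survival data but means the usual distillation guarantees apply only at
  the level of the pseudo-label construction.
- Pseudo-label imputed times inherit the teacher's baseline-hazard scale;
  when curves sit above 0.5 throughout follow-up the imputation falls back
  to the last event time, which under-disperses long survivors.
- The stability score measures selection frequency, not effect size or
  direction; strongly correlated causal genes can split their frequency.
- Elastic-net penalty selection uses a small 5-point grid per level;
  broader hyperparameter search is deliberately out of scope.
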