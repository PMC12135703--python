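# Methods

This note documents the models, defaults and judgment calls behind
`pcspanel`, in the spirit of the stability-first workflow the package
implements: every choice that could plausibly change a downstream
conclusion is either perturbed over, or recorded here with its rationale.

## Preprocessing model

qPCR reports a cycle threshold Ct per (sample, gene); lower Ct means higher
expression, and transcripts that fail to amplify within the instrument's
cycle budget are *undetected*. Expression is defined as
ΔCt = Ct(reference) − Ct(gene), so larger values mean more expressed. The
sign convention is fixed at the interface and tested.

The default perturbation set holds four pipelines:

| name | truncation | imputation | standardization |
|---|---|---|---|
| `base` | none | undetected → cycle limit (40) | no |
| `ct-limit-40` | all values clamped at 40 | (absorbed by truncation) | no |
| `base-gene-max-fill` | none | undetected → gene's max observed Ct | no |
| `ct-limit-40-standardized` | clamped at 40 | — | per-gene z-score |

Standardization statistics are fit on development rows only and reused on
held-out rows; all pipelines are pure functions of their input plus those
fitted statistics. On a complete matrix with no values above the limit the
first three pipelines coincide — they differ exactly when censoring or
out-of-range values occur, which is the situation they are designed to
stress. The registry accepts arbitrary user pipelines; the stability
machinery is defined over any perturbation set.

## Model grid and importance

Nine model specs are declared with their full hyperparameter grids
(regularization strengths 10^i for i = −3 … 3 in half-decade steps;
elastic-net mixing {0.1, 0.25, 0.5, 0.75, 0.9}; forest leaf sizes
{1, 3, 5, 10} at 500 trees; boosting learning rates {0.05, 0.1, 0.15},
leaf sizes {1, 5, 10}, depths {3, 5}, 500 estimators; rule-limit grids for
the rule-based learners). RuleFit, RF+ and FIGS are *optional* specs backed
by the third-party `imodels` package: declared so they can be plugged in,
flagged unavailable when that package is absent. The pipeline runs with any
subset of at least two available specs.

Tuning is stratified 5-fold CV maximizing AUROC, refitting on all provided
rows; ties prefer the earliest grid point, and grids are enumerated
strongest-regularization-first, so ties resolve toward the simpler model.
Linear models are fit behind a StandardScaler, making the regularization
strength comparable across features with different units.

Gene importance follows one contract per model class:

* linear models — |standardized coefficient|, i.e. per-SD log-odds;
* tree ensembles — permutation importance as the AUROC drop when a gene's
  column is shuffled (seeded, default 5 repeats, negatives floored at 0),
  evaluated on the same development rows the model was fit on.

Both choices are standard, documented and swappable; clinical covariates
participate in every fit but are never scored or ranked. In-sample
permutation importance slightly favors features the model actually used,
which is the intended reading here (what did *this fit* rely on); an
out-of-sample variant can be obtained by passing held-out rows.

## Prediction check

Each (pipeline, model) cell is scored over `n_repeats` stratified
development/test partitions (default 10, development:test = 3:1) with a
stratified inner 4-fold CV inside each development set — 40 fold-level
evaluations per cell in the reference configuration. The filter keeps a
model iff its grand-mean AUROC (mean of per-pipeline means) is at least the
reference model's grand mean, or some single pipeline lifts its mean above
the reference grand mean; the second clause encodes the view that a model
gap smaller than the preprocessing spread is not evidence of inferiority.
Ordinary logistic regression is the default reference. Comparisons use the
reference's grand mean; ties keep the model. Degenerate folds (a single
outcome class) are skipped with a warning and excluded from denominators.

## Rank tensor, stability metrics, selection

Ranks use average-tie convention (each combination's ranks sum to
G(G+1)/2 — a tested invariant). Rank SD uses the population (divide-by-N)
convention over combinations. Aggregation modes: `pcs_ensembled` (mean over
everything), `model_ensembled` (per pipeline), `model_specific` (per
pipeline × model); the pooled mean equals the combination-weighted mean of
the stratified tables (tested).

Selection keeps genes with mean rank strictly below 10 *and* top-10
proportion strictly above 0.7, ordered by mean rank, reference gene
appended. When the best unselected gene meets one criterion and misses the
other by at most a configurable slack, an extended "panel + 1" variant is
also reported — small panels often face exactly one borderline gene, and
surfacing both variants beats silently dropping it.

## Internal validation sweep

For each split, ranking mode, and panel size k, the top-k genes *per that
split's own development-derived ranking* plus the clinical covariates are
refit and scored on that split's test rows. Using per-split rankings (never
the pooled ranking) prevents the sweep from inheriting selection optimism.
k = 0 (clinical-only) is allowed as a baseline. The report gives the
argmax-k per stratum, the AUROC range across pipelines at each k (the
preprocessing-robustness diagnostic), and each k's drop from the best.

## Final model, recalibration, clinical utility

The locked model is ridge-logistic on panel genes + clinical covariates
(age, race, family history, abnormal DRE, prior negative biopsy, PSA;
prostate volume optional), C tuned by 5-fold CV over the standard grid on
the full development cohort. Coefficients, standardization statistics and
calibration parameters serialize to JSON; a locked model rejects further
recalibration. Because C is tuned for discrimination, not calibration
scale, strong shrinkage can be chosen; the subsequent logistic
recalibration (`logit p = a + b·LP`, maximum likelihood) restores the
scale, so a large fitted slope is expected behavior, not a defect. With
b > 0 recalibration is strictly monotone and leaves AUROC untouched
(tested).

The sensitivity-anchored threshold is the largest threshold whose
sensitivity meets the target (ties at the threshold call positive), which
maximizes specificity subject to the floor. Per-1000 quantities round to
the nearest integer; "cancers missed per 1000" uses the high-grade patients
as denominator (FN/(FN+TP)). Metrics with empty denominators report as
undefined (None), never NaN.

The minimum test tradeoff is a pluggable formula object; the default is
MTT = 1/(prevalence · ΔAUROC), which captures the hyperbolic blow-up as two
panels' discrimination converges. Uncertainty in the AUROC gap maps to an
MTT interval by evaluating the formula at gap ± uncertainty. Published MTT
figures computed under other approximations will not numerically match the
default formula; supply a custom formula for those.

## Synthetic cohort generator

The generator emulates a biomarker-development study: latent per-gene
expression is multivariate normal with block-diagonal correlation (blocks
of 6, within-block r = 0.3 by default), the binary outcome follows a
logistic model in the planted signal genes and clinical covariates, and
the intercept is solved by bisection so realized prevalence matches a
target (|expected − target| < 1e-3). Defaults mirror a development cohort
of n = 761 with assumed 35% high-grade prevalence and a validation-style
cohort of n = 743 at 20%; 54 candidate genes plus the reference.

Ct values are `gene_baseline − 1.5·Z + N(0, 1)`, right-censored at 40
cycles. Gene baselines jitter around 30 cycles (SD 5, clipped at ±1.5 SD):
the jitter makes a realistic minority of entries hit the detection limit so
the censoring machinery is actually exercised, and the clip reflects assay
design — a candidate marker that were mostly undetectable would never have
been nominated onto the panel. The reference gene is abundant (baseline 25,
SD 0.5, no outcome effect). Clinical marginals: age ~ N(62, 8); PSA ~
lognormal truncated to the 3–10 ng/mL biopsy-referral band; prostate volume
~ lognormal (median 45 mL); binary covariates Bernoulli with conventional
prevalences. Continuous covariates enter the outcome model as within-sample
z-scores, binaries as indicators, with default log-odds coefficients of
±0.2–0.5.

The six default planted genes sit in six different blocks (so each has five
correlated decoys) with log-odds effects 2.0 … 1.5 per SD. The ladder is
calibrated so the planted markers reproduce the stability profile the
generator is meant to emulate — all six stably in the top 10 across
preprocessing/model/split combinations, *including* tree models, whose
permutation importances need a larger per-gene effect than linear
coefficients do at n ≈ 750, and clearing the best-of-48-decoys order
statistic with margin across cohort draws. These are strong markers
(OR ≈ 4.5–7.4 per SD), plausible for the top tier of validated urine
biomarkers; with weaker effects the exact top-6 recovery becomes a power
question rather than a machinery check.

What the generator does *not* model — and hence what passing tests do not
establish about real data: plate/batch effects, technical replicates,
amplification-efficiency variation, non-Gaussian expression tails,
correlation between clinical covariates and gene expression, and
covariate-dependent censoring. Recovery results on synthetic cohorts
certify the ranking/selection machinery, not field performance.

## Problem sizes in the shipped tests

The reference configuration (4 pipelines × 6 models × 10 splits, full
grids, 500-tree ensembles) is what a real analysis would run. The shipped
test and acceptance runs use the package's scaled-down configurations —
3 development/test repeats, 100-tree forests with fixed leaf size, 3-point
regularization grids, 3 permutation repeats — which keep the full-scale
(n = 750, 54-gene, 10-seed) recovery check and the 240-combination
bookkeeping check to a few minutes on one CPU while exercising every code
path at study-realistic sample sizes.

## Known limitations

* The prediction filter compares mean AUROC only; AUPRC and accuracy are
  reported but not used for filtering.
* Permutation importance on strongly correlated features spreads credit;
  block decoys of a very strong gene can rank above a weak true signal in
  tree models. The multi-model ensemble mitigates but does not remove this.
* Exact recovery of a planted panel is only guaranteed in the
  strong-effect regime; near the detection boundary the stability metrics
  degrade gracefully (that is their job) but top-k sets become unstable.
* The MTT default formula is deliberately simple; decision-curve analysis
  beyond the MTT is out of scope.
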