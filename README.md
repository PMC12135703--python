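# pcspanel

Stability-driven biomarker panel selection for qPCR-style gene-expression
cohorts, with a full clinical risk-model workflow on top: perturbed
preprocessing pipelines, a prediction-checked model ensemble, gene rankings
aggregated across every perturbation, panel-size internal validation, and a
final locked ridge-logistic risk score with logistic recalibration and
sensitivity-anchored clinical-utility evaluation.

## Who this is for

Biostatisticians and translational researchers distilling a large candidate
biomarker panel (say, 54 qPCR assays plus a reference gene such as *KLK3*)
into a small, assay-friendly panel for a binary clinical outcome (e.g.
high-grade prostate cancer, Grade Group ≥ 2), while guarding against the
quiet dependence of "the selected genes" on arbitrary preprocessing and
modeling choices.

## The method

Raw cycle-threshold (Ct) values are converted to expression by ΔCt
normalization against the reference gene, `expr(s, g) = Ct(s, ref) − Ct(s, g)`
(lower Ct = higher expression), after truncation/imputation of undetected
entries. Because truncation limits, imputation rules and standardization are
judgment calls, the package applies a *set* of preprocessing pipelines (four
documented defaults, user-extensible) and treats them as perturbations.

Selection then runs in three stages:

1. **Prediction check.** Every (pipeline, model) cell of a model grid
   (logistic, L1/L2/elastic-net logistic, random forest, gradient boosting,
   plus optional RuleFit/RF+/FIGS) is scored by inner *k*-fold CV repeated
   over stratified development/test splits, hyperparameters tuned by 5-fold
   CV. Models whose mean AUROC falls below ordinary logistic regression are
   dropped — unless some pipeline lifts them above it, in which case the
   preprocessing uncertainty outweighs the model gap and they are kept.
2. **Stability-driven ranking.** For every (pipeline, kept model, split)
   combination — 4 × 6 × 10 = 240 in the reference configuration — gene
   importances (|standardized coefficient| for linear models, permutation
   AUROC drop for tree ensembles) are converted to ranks. Per gene, the rank
   distribution over combinations yields the mean rank, rank SD, and the
   proportion of combinations ranked in the top 5/10/17.
3. **Panel selection.** Genes with mean rank < 10 that sit in the top 10 in
   more than 70% of combinations form the panel; the reference gene is
   appended for assay accounting, and a borderline next gene can be emitted
   as an extended-panel variant.

An internal validation sweeps the panel size *k* (per-split rankings only —
no test leakage) to confirm the stability-chosen size. The final panel is
fit as a ridge-logistic risk model, recalibrated to a deployment cohort's
prevalence by maximum-likelihood refit of `logit(p) = a + b·LP`, locked, and
evaluated at the largest threshold retaining a target sensitivity (default
95%), reporting specificity, NPV, PPV and biopsies avoided per 1000. The
minimum test tradeoff `MTT = 1 / (prevalence · ΔAUROC)` (pluggable formula)
quantifies when a larger assay earns its extra collection cost.

A seeded synthetic-cohort generator (`pcspanel.synthetic`) plants known
signal genes in block-correlated expression with right-censored Ct values
and realistic clinical covariates, so the whole pipeline is testable end to
end without patient data.

## Worked example

`examples/` holds one narrative script per capability. For instance,
ranking and selection on a 12-gene cohort with two planted genes
(`python examples/rank_and_select.py`) prints:

```
rank tensor: 4 pipelines x 2 models x 3 splits = 24 combinations
      mean_rank  rank_sd  prop_top3  prop_top10
gene
G01       1.000    0.000      1.000       1.000
G05       2.000    0.000      1.000       1.000
G04       4.417    2.129      0.667       1.000
...
selected panel: ['G01', 'G05'] + reference KLK3 (3 measured genes)
planted truth was: ['G01', 'G05']
```

The two planted genes rank 1–2 with zero rank SD across all 24
perturbation combinations; the correlated decoy G04 (same latent block as
G01) trails with an unstable rank and is excluded by the mean-rank
threshold. Evaluating a locked model on a 20%-prevalence validation-style
cohort (`python examples/risk_model_evaluation.py`) prints the clinical
operating point, e.g.:

```
locked 6-gene model: sensitivity 95.2% | specificity 44.3% (265/598) |
NPV 97.4% (265/272) | PPV 29.3% (138/471) | biopsies avoided per 1000: 443
```

i.e. at a threshold keeping ≥95% of high-grade cancers, 44% of the men
without high-grade disease would have been spared a biopsy.

There is also a thin CLI over the same library calls, staged through files
so the model can be locked on disk before any evaluation cohort is touched:

```bash
pcspanel simulate --config run.yaml --out results/
pcspanel check    --config run.yaml --out results/
pcspanel rank     --config run.yaml --out results/
pcspanel sweep    --config run.yaml --out results/
pcspanel finalize --config run.yaml --out results/
pcspanel evaluate --config run.yaml --out results/
```

## Layout

- `src/pcspanel/` — library (`synthetic`, `preprocess`, `models`,
  `prediction_check`, `stability`, `panel_sweep`, `risk`, `io`, `cli`)
- `examples/` — one short narrative script per capability
- `tests/` — unit, property and end-to-end acceptance suites
- `docs/methods.md` — modeling assumptions, parameter defaults, numerical
  choices, and known limitations
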