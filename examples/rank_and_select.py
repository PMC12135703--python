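"""Stages 2-3: build the gene-rank tensor and select the stable panel.

Fits every (pipeline, model, split) combination on a synthetic cohort with
two planted genes, converts each fit's gene importances to ranks, summarizes
each gene's rank distribution (mean, SD, proportion in the top 10), and
selects the genes that are both highly and stably ranked.  The planted
genes top the summary; block-correlated decoys (e.g. genes sharing a
latent block with a strong planted gene) trail them, which is why the
selection uses a mean-rank threshold and not just top-k.  The reference
gene is appended for assay accounting.
"""

from pcspanel import SimulationConfig, build_rank_tensor, make_splits, \
    select_panel, simulate_cohort, stability_summary
from pcspanel.models import available_models
from pcspanel.preprocess import default_pipeline_set

cohort = simulate_cohort(SimulationConfig(
    n_samples=300, n_genes=12, block_size=4,
    signal_effects={"G01": 1.8, "G05": 1.4}, seed=3))
plan = make_splits(cohort.n_samples, cohort.outcome, n_repeats=3,
                   inner_folds=3, seed=3)

specs = {s.name: s for s in available_models()}
kept = [specs["ridge-logistic"].with_grid(clf__C=[0.1, 1.0]),
        specs["lasso-logistic"].with_grid(clf__C=[0.1, 1.0])]
tensor = build_rank_tensor(cohort, default_pipeline_set(), kept, plan,
                           tune_folds=3, seed=3)
print(f"rank tensor: {tensor.values.shape[0]} pipelines x "
      f"{tensor.values.shape[1]} models x {tensor.n_repeats} splits "
      f"= {tensor.n_valid_combinations()} combinations")

summary = stability_summary(tensor, top_m=(3, 10))
print(summary.head(6).round(3).to_string())

panel = select_panel(summary, reference_gene="KLK3",
                     max_mean_rank=4, min_prop_top10=0.7)
print(f"\nselected panel: {panel.genes} + reference {panel.reference_gene} "
      f"({panel.measured_genes} measured genes)")
print(f"planted truth was: {sorted(cohort.truth['signal_effects'])}")
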