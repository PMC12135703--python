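"""Generate a synthetic qPCR biomarker cohort with known planted truth.

Draws a development-style cohort (761 patients, 54 candidate genes plus the
KLK3 reference) and writes ct.csv / clinical.csv / truth.json.  The printed
numbers are the cohort's realized high-grade prevalence, the fraction of Ct
entries censored at the 40-cycle detection limit, and the planted signal
genes with their log-odds effect sizes — the ground truth every downstream
stage is later judged against.
"""

from pcspanel import SimulationConfig, planted_truth, simulate_cohort
from pcspanel.synthetic import write_cohort

config = SimulationConfig(n_samples=761, seed=1)
cohort = simulate_cohort(config)
write_cohort(cohort, "scratch/example_cohort")

print(f"cohort: {cohort.n_samples} samples x {len(cohort.ct.genes)} genes "
      f"(incl. reference {cohort.ct.reference_gene})")
print(f"realized high-grade prevalence: {cohort.outcome.mean():.3f} "
      f"(target {config.prevalence_target})")
print(f"censored Ct entries: {cohort.ct.mask.to_numpy().mean():.3%}")
print("planted signal genes (gene, log-odds per SD):")
for gene, beta in planted_truth(config):
    print(f"  {gene}: {beta:+.2f}")
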