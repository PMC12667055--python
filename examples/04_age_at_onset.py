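"""Case-only age-at-onset analysis on a synthetic cohort.

Simulates a cohort at the study's effect sizes (wild-type median onset 72 y,
PTV shift -10 y, HPV shift -8 y, APOE-e4 shifting onset -5.5 y per allele),
then estimates Kaplan-Meier onset curves per category, medians with 10-90%
inter-percentile ranges, and median shifts vs wild-type with bootstrap CIs.
"""

import numpy as np

from sorlvar import (
    SimulationParams,
    aao_summaries,
    carrier_categories,
    classify_all,
    load_architecture,
    load_ruleset,
    simulate_cohort,
    simulate_variant_table,
    synthetic_reference_sequence,
)

arch = load_architecture()
arch.reference_sequence = synthetic_reference_sequence(arch, seed=1)
rules = load_ruleset()
variants, truth = simulate_variant_table(arch, rules, 250, seed=1)
params = SimulationParams(n_cases=18500, n_controls=21500, seed=11)
cohort = simulate_cohort(params, variants, truth)

cats = carrier_categories(cohort, classify_all(cohort, arch, rules))
print(f"{'group':10s} {'n':>6s} {'median (10-90% IPR)':>22s} "
      f"{'delta vs WT (95% CI)':>24s}  log-rank p")
for s in aao_summaries(cohort, cats, n_boot=1000, seed=0):
    if s.n == 0:
        continue
    ipr = f"{s.median_aao:.0f} ({s.p10:.0f} - {s.p90:.0f})"
    if s.delta_vs_wt is None:
        delta, p = "(reference)", ""
    else:
        delta = f"{s.delta_vs_wt:+.1f} ({s.delta_ci[0]:.1f}, {s.delta_ci[1]:.1f})"
        p = f"{s.logrank_p_vs_wt:.2g}"
    print(f"{s.label:10s} {s.n:>6d} {ipr:>22s} {delta:>24s}  {p}")

print(
    "\nPTV and HPV carriers develop AD roughly 10 and 8 years earlier than"
    "\nSORL1 wild-type cases; the other categories sit on the wild-type curve."
)
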