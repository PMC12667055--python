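"""Reproduce the published burden odds ratios from the published counts.

The study's carrier counts per category (and the cohort totals: 18,959 AD
cases of which 6,155 early-onset, 21,893 controls) are enough to rebuild
every 2x2 table; the cross-product odds ratio with a log-scale Wald CI and a
two-sided Fisher exact test then reproduce the printed association results.
"""

import pandas as pd

from sorlvar.published import published_burden_table

pd.set_option("display.width", 120)

table = published_burden_table(
    labels=["PTV", "HPV", "HPV_VPS10p", "HPV_YWTD", "HPV_CR",
            "HPV_CR_cysteines_ONC"]
)
table["OR (95% CI)"] = table.apply(
    lambda r: f"{r.odds_ratio:.1f} ({r.ci_low:.1f} - {r.ci_high:.1f})"
    if pd.notna(r.odds_ratio) else "NA", axis=1,
)
print(table[["label", "stratum", "case_carriers", "control_carriers",
             "OR (95% CI)", "p_fisher"]].to_string(index=False))

print(
    "\nPTV carriers have a ~17-fold increased odds of AD overall and ~35-fold"
    "\nfor early-onset AD; high-priority missense carriers ~6- and ~10-fold."
    "\nEOAD and LOAD strata are always compared against the full control set."
)
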