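"""Classify a handful of annotated variants into priority categories.

Builds variant records by hand (HGVS protein change + REVEL/LOFTEE/MAF
annotations), classifies them against the packaged rules, and prints the
category and the rule that fired.  PTV > HPV > MPV > LPV > NPV is the
priority order; variants at or above 0.05% MAF route to the less-rare
analysis and exon-1 variants are excluded.
"""

from sorlvar import (
    Category,
    ChangeKind,
    Cohort,
    CohortIndividual,
    ProteinChange,
    VariantRecord,
    classify_variant,
    load_architecture,
    load_ruleset,
)

arch = load_architecture()
rules = load_ruleset()
# a stand-in cohort: only its size matters here (sample-MAF fallback)
cohort = Cohort(individuals=[CohortIndividual(f"I{k}", "control", 70.0)
                             for k in range(1000)])


def record(hgvs=None, kind=ChangeKind.MISSENSE, revel=None, loftee=0,
           exon=None, maf=1e-5):
    change = None
    if hgvs:
        ref, pos, alt = hgvs
        change = ProteinChange(ref, pos, alt, kind)
    return VariantRecord("11:121300000:A>G", hgvs_p=change, revel=revel,
                         loftee_flag=loftee, exon=exon,
                         gnomad_nonneuro_popmax_maf=maf)


examples = [
    ("p.R744* (LOFTEE)", record(("R", 744, "*"), ChangeKind.NONSENSE, loftee=1)),
    ("p.W2203* (exon 48)", record(("W", 2203, "*"), ChangeKind.NONSENSE, exon=48)),
    ("p.Y391C", record(("Y", 391, "C"), revel=0.43)),
    ("p.D1108N", record(("D", 1108, "N"), revel=0.55)),
    ("p.Y1816C", record(("Y", 1816, "C"), revel=0.62)),
    ("p.S564G REVEL 0.8", record(("S", 564, "G"), revel=0.80)),
    ("p.E1500K REVEL 0.8", record(("E", 1500, "K"), revel=0.80)),
    ("p.E1500K REVEL 0.1", record(("E", 1500, "K"), revel=0.10)),
    ("p.A528T MAF 3.6%", record(("A", 528, "T"), revel=0.7, maf=0.036)),
]

for name, rec in examples:
    cv = classify_variant(rec, arch, rules, cohort)
    rule = f"  [{cv.triggering_rule}]" if cv.triggering_rule else ""
    print(f"{name:22s} -> {cv.category.name}{rule}")

print(
    "\nTruncating variants are PTV; missense at homologous pathogenic"
    "\npositions (calcium cage, tyrosine corner, loop cysteines) are HPV"
    "\nregardless of REVEL; in VPS10p/10CC a REVEL >= 0.5 gate stands in for"
    "\nthe missing homology evidence; high-REVEL missense elsewhere is LPV."
)
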