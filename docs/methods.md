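# Methods

This note records the models, conventions and design choices behind
`sorlvar`, and what the synthetic experiments do and do not demonstrate.

## Domain model

The protein is represented as an ordered, gap-free partition of residues
1..2214 into nine segments (signal peptide 1–28, pro-domain 29–81, VPS10p
82–617, 10CC 618–753, YWTD 754–1013, EGF 1014–1074, CR cluster 1075–1550,
3Fn cassette 1551–2121, transmembrane/tail 2122–2214), plus repeat units
(CR, 3Fn, YWTD blades, VPS10p loops L1/L2) that carry their own 1-based
within-repeat coordinate system.  All rules are written in within-repeat
coordinates, so the single load-bearing operation is
`locate_residue`: global residue → (segment, repeat, repeat position).

Per-repeat boundaries are not published at residue resolution.  The default
config therefore anchors repeat starts to independently stated
(residue, repeat position) facts — e.g. the 3rd 3Fn domain starts at
1816 − 83 + 1 = 1734 because the tyrosine-corner residue 1816 is repeat
position 83 — and interpolates the rest.  Anchors are re-checked at load
time and a violated anchor is a hard error.  Two consequences are accepted
deliberately:

* anchored starts can overhang their parent segment boundary (3Fn1 begins at
  1541, ten residues before the stated cassette start); overhangs ≤ 10
  residues load with a warning rather than an error, preserving both printed
  facts;
* interpolated CR repeats vary in length (36–50 residues), so alignment
  positions near 47–48 exist only in the longer repeats.  Rules simply
  cannot fire at positions beyond a repeat's length.  Boundaries are plain
  config entries and are meant to be refined by users with structural
  alignments in hand; the shipped set covers the anchored positions exactly
  and everything else approximately.

## Classification

Decision order (first hit wins): exclusion region (exon 1 / residues 1–95,
excluded for differential coverage) → rarity gate → PTV → non-missense
residual → high-priority rules → moderate rules → REVEL-based LPV → NPV.

Conventions worth stating:

* **Rarity.**  Effective MAF is the GnomAD non-neuro popmax frequency;
  variants absent from GnomAD fall back to the in-sample *carrier* frequency
  (carriers / individuals, not alleles / 2N — the convention under which 21
  carriers among 40,852 individuals crosses the 0.05% threshold; an
  allele-based denominator is available behind a flag).  `rare` means
  strictly < 0.05%.
* **REVEL gate.**  The threshold is ≥ 0.5 and applies as an HPV rule inside
  VPS10p and 10CC and as the LPV rule outside VPS10p.  A missense variant
  whose only route to priority is an unevaluable (missing) REVEL score is
  conservatively NPV with a `revel_unannotated` flag.
* **Splice triage.**  Splice variants not flagged by LOFTEE but with a
  splice-prediction score ≥ 0.2 (the high-recall SpliceAI cutoff) are
  flagged for manual review, never auto-promoted to PTV: promotion is a
  curation decision.
* **Merging.**  Juxtaposed substitutions confirmed in cis with identical
  carriers merge into one double substitution with the pair's minimum REVEL
  (conservative) and minimum MAF; unknown-phase pairs stay separate and are
  flagged.
* **Carrier grouping.**  PTV > HPV > MPV > LPV > NPV > less-rare; this order
  is total, so multi-variant carriers group deterministically.  Variants in
  exclusion regions never contribute to grouping.

## Burden association

The point estimate is the sample cross-product odds ratio with the log-scale
Wald 95% CI, `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))` — this is the pairing
that reproduces both the published point estimates and intervals from the
published carrier counts.  Any zero cell reports NA (Haldane–Anscombe 0.5
correction available but off by default).  EOAD is onset < 65 and LOAD
≥ 65 (the boundary is a parameter; the source material uses both "< 65" and
"≤ 65" in different places), and both strata are compared against the full,
unstratified control set.

The two-sided Fisher p is the hypergeometric probability of all tables at
most as probable as the observed one.  For supports up to 1,000 it is
computed in exact integer arithmetic (`math.comb`), eliminating
floating-point tie ambiguity; larger supports delegate to scipy.  The
Bonferroni family defaults to the number of tests emitted by one scan and is
overridable, since the family used for the published adjusted p-values is
not stated.

Adjusted analyses fit logistic regressions of case status on the carrier
indicator, APOE-ε4 allele count and PC1–PC6 by maximum likelihood (Newton,
tolerance 1e-8, 100 iterations, BFGS fallback for flat likelihoods);
quasi-separation on the carrier indicator is detected and reported as a
flagged result with NA standard error.  The APOE interaction test is a
likelihood-ratio test of the additive model against one adding
carrier × ε4-dose, χ² with df = 1.

## Age at onset

The case-only design treats every case as an event at their onset age (no
censoring; censoring is supported for synthetic experiments).  Curves are
product-limit estimates with R-`survival`-style log-transformed Greenwood
pointwise CIs.  Quantiles use the convention *smallest event time t with
S(t) ≤ 1 − q*; the summary reports the median and the 10%/90% onset
quantiles.  Ages recorded as "> 89" are set to 90 at ingest, before any
survival computation.

The CI method for median onset differences is not stated in the source
material; `sorlvar` uses a percentile bootstrap over individuals (default
2,000 resamples, seeded), chosen as reproducible and assumption-light.
Exact reproduction of published onset CIs is therefore not claimed — it
would require individual-level data in any case.

## Synthetic cohort generator

The generator emulates the assembled case/control study:

* **Disease model.**  `logit P(case) = b₀ + ln OR_category + e4·ln OR_APOE`.
  Category draw probabilities are calibrated by fixed-point iteration so the
  realized carrier frequency *among controls* matches the configured
  `category_control_prevalence` (high-OR categories must be more common in
  the population than among controls), and b₀ is calibrated so the expected
  case fraction matches the requested cohort composition.
* **Onset.**  Case AAO = 72 + category shift + ε4-dose × (−5.5) + truncated
  normal noise (σ = 12, bounds 30–105); the defaults give a wild-type median
  of 72 with a 10–90% spread of ≈30 years and an EOAD fraction near 0.32.
  `eoad_fraction` is a declared consistency target, not a dial: the realized
  fraction emerges from the onset model and a large mismatch warns.
  Controls get a truncated-normal age at last screening (71 ± 16, bounds
  40–105).
* **Defaults.**  n = 18,959 cases / 21,893 controls; control carrier
  frequencies per category at the study's values (e.g. PTV 6/21,893); odds
  ratios 17/6/1.5/1.2/1.1 for PTV/HPV/MPV/LPV/NPV; ε4 allele frequency 0.15
  with OR 3 per allele; PCs are pure noise; carrier dosages are 1.  Control
  APOE missingness is available as a parameter (default 0).
* **Variant table.**  Deterministic per seed; covers every rule class at
  least once with truth labels recorded at generation time.  All generated
  variants carry a GnomAD-style MAF so truth labels do not depend on
  realized carrier counts; the sample-MAF fallback is exercised by dedicated
  unit tests instead.  The reference sequence attached to the architecture
  is synthetic — a random sequence carrying exactly the residue identities
  the rules presuppose (cysteines only at designated positions, D/D/D/E
  cages, the YWTD tetrad, the 3Fn tyrosine corner) — and is labelled as
  such; it is not the real protein sequence.

What passing synthetic tests shows: the pipeline classifies rule-conforming
variants exactly, and the estimators recover generating parameters at the
study's sample size with nominal interval coverage.  What it does not show:
robustness to annotation noise (mis-stated reference residues, transcript
mismatches), linkage between variants, relatedness, cohort heterogeneity, or
ascertainment effects — none of which the generator simulates.  The logistic
sampling model makes the configured ORs conditional (given APOE) effects;
marginal 2×2 ORs are slightly attenuated by non-collapsibility, which is why
recovery experiments read the covariate-adjusted estimate, and why onset
shifts are recovered within APOE strata (the case-only contrast across
strata is collider-biased).

## Evaluation experiment sizes

The replicated experiments use 100 cohorts of 40,000 individuals for
interval-coverage checks, 200 cohorts for null calibration (burden p-values
of a null category against Uniform(0,1) by Kolmogorov–Smirnov), bootstrap
size 1,000 inside replicated experiments (2,000 as the analysis default),
and exhaustive Fisher verification over all 635,376 tables with N ≤ 60.
These sizes give stable checks at a few minutes of single-CPU runtime.

## Known limitations

* The shipped rule set covers the residue classes stated in the main
  analysis; the complete black/grey alignment annotation of the original
  compendium is not public, so some true high-priority positions are
  necessarily absent from the default config (they can be added as config
  entries).
* One published repeat-position statement (p.G1681D at 3Fn position 36) is
  inconsistent with the anchors used for 3Fn2; the anchors win and the
  discrepancy is documented in the default config rather than silently
  averaged.
* The less-rare (MAF > 0.05%) variants are routed to their own label but the
  dosage-based logistic single-variant analysis the source applied to them
  is out of scope.
* No penetrance estimation: case-only onset distributions from an
  EOAD-enriched assembled sample are not population-representative, and the
  package makes no attempt to correct for that.
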