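"""Rule-based priority classification of rare SORL1 coding variants.

Variants are assigned to one of the closed categories

    PTV > HPV > MPV > LPV > NPV > LESS_RARE   (plus EXCLUDED and WT)

by domain-mapping of disease mutations (DMDM): residues homologous to known
pathogenic positions in related receptor families (LDLR-family calcium cages,
CR-domain cysteine patterns, the YWTD tetrad, the 3Fn tyrosine corner, ...)
are high priority regardless of in-silico scores, while the VPS10p/10CC
region — for which no homologous disease mutations are available — falls back
to a REVEL score gate.  Truncating variants (LOFTEE-flagged, or rescued
nonsense/frameshift in the final exon) are PTV; variants at or above the
rarity threshold are routed to the less-rare analysis instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping, Optional, Sequence, Union

from .domain import DomainArchitecture, ResidueContext, load_architecture, locate_residue
from .ingest import ChangeKind, Cohort, CohortIndividual, ProteinChange, VariantRecord, carrier_set, effective_maf

__all__ = [
    "Category",
    "ResidueRule",
    "PriorityRuleSet",
    "ClassifiedVariant",
    "load_ruleset",
    "is_ptv",
    "cysteine_change",
    "classify_variant",
    "classify_all",
    "assign_carrier_category",
    "carrier_categories",
]


class Category(IntEnum):
    """Priority categories, ordered so max() picks the highest priority."""

    WT = 0
    LESS_RARE = 1
    EXCLUDED = 2
    NPV = 3
    LPV = 4
    MPV = 5
    HPV = 6
    PTV = 7

    def __str__(self) -> str:  # TSV-friendly
        return self.name


#: Categories that enter the rare-variant burden analysis.
RARE_CATEGORIES = (Category.PTV, Category.HPV, Category.MPV, Category.LPV,
                   Category.NPV)


@dataclass(frozen=True)
class ResidueRule:
    """One DMDM residue rule.

    ``scope`` is ``"segment:<name>"`` or ``"repeat:<class>"``; for repeat
    scopes ``positions`` lists the within-repeat positions the rule covers
    (or "any").  ``trigger`` is one of ``fixed_position``,
    ``cysteine_gain_or_loss`` or ``revel_at_least``.
    """

    label: str
    scope: str
    trigger: str
    positions: Union[Sequence[int], str] = "any"
    priority: str = "high"

    def __post_init__(self) -> None:
        kind, _, name = self.scope.partition(":")
        if kind not in ("segment", "repeat") or not name:
            raise ValueError(f"rule {self.label}: bad scope {self.scope!r}")
        if self.trigger not in ("fixed_position", "cysteine_gain_or_loss",
                                "revel_at_least"):
            raise ValueError(f"rule {self.label}: bad trigger {self.trigger!r}")
        if self.trigger == "fixed_position" and (
            self.positions == "any" or not len(self.positions)
        ):
            raise ValueError(
                f"rule {self.label}: fixed_position requires explicit positions"
            )

    def scope_matches(self, ctx: ResidueContext) -> bool:
        kind, _, name = self.scope.partition(":")
        if kind == "segment":
            return ctx.segment == name
        if ctx.repeat_class != name:
            return False
        if self.positions == "any":
            return True
        return ctx.repeat_position in tuple(self.positions)


@dataclass
class PriorityRuleSet:
    """Thresholds plus the high/moderate residue rules of the DMDM scheme."""

    revel_threshold: float = 0.5
    maf_threshold: float = 0.0005
    splice_review_threshold: float = 0.2
    dosage_threshold: float = 0.5
    ptv_exon_rescue: tuple[int, ...] = (48,)
    high_rules: list[ResidueRule] = field(default_factory=list)
    moderate_rules: list[ResidueRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        for thr in (self.revel_threshold, self.maf_threshold,
                    self.splice_review_threshold):
            if not (0.0 <= thr <= 1.0):
                raise ValueError(f"threshold out of [0,1]: {thr}")
        for rule in self.high_rules:
            if rule.priority != "high":
                raise ValueError(f"rule {rule.label} in high_rules is not high")
        for rule in self.moderate_rules:
            if rule.priority != "moderate":
                raise ValueError(
                    f"rule {rule.label} in moderate_rules is not moderate"
                )

    def validate_against(self, arch: DomainArchitecture) -> None:
        seg_names = {s.name for s in arch.segments}
        rep_classes = {r.repeat_class for r in arch.repeats}
        for rule in self.high_rules + self.moderate_rules:
            kind, _, name = rule.scope.partition(":")
            known = seg_names if kind == "segment" else rep_classes
            if name not in known:
                raise ValueError(
                    f"rule {rule.label} references unknown {kind} {name!r}"
                )


def load_ruleset(config: Optional[Union[Mapping, str]] = None) -> PriorityRuleSet:
    """Build a rule set from a config dict/path (default: packaged rules)."""
    from .domain import _as_config_dict

    cfg = _as_config_dict(config)
    rules_cfg = cfg.get("rules", cfg)  # accept whole config or rules block

    def _mk(entries, priority):
        return [
            ResidueRule(
                label=e["label"], scope=e["scope"], trigger=e["trigger"],
                positions=e.get("positions", "any"), priority=priority,
            )
            for e in entries
        ]

    return PriorityRuleSet(
        revel_threshold=float(rules_cfg.get("revel_threshold", 0.5)),
        maf_threshold=float(rules_cfg.get("maf_threshold", 0.0005)),
        splice_review_threshold=float(rules_cfg.get("splice_review_threshold", 0.2)),
        dosage_threshold=float(rules_cfg.get("dosage_threshold", 0.5)),
        ptv_exon_rescue=tuple(rules_cfg.get("ptv_exon_rescue", [48])),
        high_rules=_mk(rules_cfg.get("high_rules", []), "high"),
        moderate_rules=_mk(rules_cfg.get("moderate_rules", []), "moderate"),
    )


@dataclass
class ClassifiedVariant:
    record: VariantRecord
    category: Category
    subcategory: Optional[str] = None
    triggering_rule: Optional[str] = None
    needs_manual_review: bool = False
    maf: Optional[float] = None
    maf_source: Optional[str] = None
    flags: set[str] = field(default_factory=set)


# -- elementary predicates ----------------------------------------------


def is_ptv(record: VariantRecord, rules: PriorityRuleSet) -> tuple[bool, bool]:
    """(is_ptv, needs_review).

    LOFTEE flag 1 is a PTV.  Nonsense/frameshift in a rescue exon (the final
    exon, which LOFTEE does not annotate) are PTV too.  Splice variants with
    LOFTEE 0 but a splice-prediction score above the review threshold are NOT
    promoted automatically: they return (False, True) and promotion is an
    explicit curation decision.
    """
    if record.loftee_flag == 1:
        return True, False
    kind = record.change_kind
    if kind in (ChangeKind.NONSENSE, ChangeKind.FRAMESHIFT) and (
        record.exon is not None and record.exon in rules.ptv_exon_rescue
    ):
        return True, False
    if (
        kind is ChangeKind.SPLICE
        and record.splice_score is not None
        and record.splice_score >= rules.splice_review_threshold
    ):
        return False, True
    return False, False


def cysteine_change(
    refseq: Optional[str], change_sub: tuple[str, int, str]
) -> Optional[str]:
    """'gain' | 'loss' | None for one substitution (ref, position, alt).

    When a reference sequence is supplied, the stated reference residue must
    match it (data-integrity check).
    """
    ref, pos, alt = change_sub
    if refseq is not None:
        if pos > len(refseq):
            raise IndexError(f"residue {pos} beyond reference length {len(refseq)}")
        if refseq[pos - 1] != ref:
            raise ValueError(
                f"reference mismatch at residue {pos}: sequence has "
                f"{refseq[pos - 1]}, variant states {ref}"
            )
    if ref != "C" and alt == "C":
        return "gain"
    if ref == "C" and alt != "C":
        return "loss"
    return None


def _rule_fires(
    rule: ResidueRule,
    ctx: ResidueContext,
    sub: tuple[str, int, str],
    revel: Optional[float],
    rules: PriorityRuleSet,
    refseq: Optional[str],
) -> Optional[str]:
    """Subcategory label if the rule fires for this substitution, else None."""
    if not rule.scope_matches(ctx):
        return None
    if rule.trigger == "fixed_position":
        return rule.label
    if rule.trigger == "cysteine_gain_or_loss":
        change = cysteine_change(refseq, sub)
        return f"{rule.label}_{change}" if change else None
    if rule.trigger == "revel_at_least":
        if revel is not None and revel >= rules.revel_threshold:
            return rule.label
        return None
    return None


# -- classification ------------------------------------------------------


def classify_variant(
    record: VariantRecord,
    arch: DomainArchitecture,
    rules: PriorityRuleSet,
    cohort: Cohort,
) -> ClassifiedVariant:
    """Assign one variant its priority category with rule provenance.

    Decision order: exclusion region -> rarity gate -> PTV -> non-missense
    residual -> high rules (fixed positions, cysteine gains/losses, the
    VPS10p/10CC REVEL gate) -> moderate rules -> REVEL-based LPV (outside
    VPS10p) -> NPV.  A missense variant whose only route to priority would be
    an unevaluable REVEL score is conservatively NPV with a flag.
    """
    flags: set[str] = set(record.flags)
    if cohort.is_excluded(record):
        return ClassifiedVariant(record, Category.EXCLUDED, flags=flags)

    maf, source = effective_maf(record, cohort, rules.dosage_threshold)
    base = dict(maf=maf, maf_source=source)
    if maf >= rules.maf_threshold:
        return ClassifiedVariant(record, Category.LESS_RARE, flags=flags, **base)

    ptv, review = is_ptv(record, rules)
    if ptv:
        return ClassifiedVariant(record, Category.PTV, flags=flags, **base)

    change = record.hgvs_p
    if change is None or change.kind is not ChangeKind.MISSENSE:
        if review:
            flags.add("splice_review")
        return ClassifiedVariant(
            record, Category.NPV, needs_manual_review=review, flags=flags, **base
        )

    refseq = arch.reference_sequence
    subs = change.substitutions()
    contexts = [locate_residue(arch, pos) for _, pos, _ in subs]
    revel = record.revel
    revel_needed = False

    for bucket, category in ((rules.high_rules, Category.HPV),
                             (rules.moderate_rules, Category.MPV)):
        for rule in bucket:
            for ctx, sub in zip(contexts, subs):
                if rule.trigger == "revel_at_least" and revel is None:
                    if rule.scope_matches(ctx):
                        revel_needed = True
                    continue
                label = _rule_fires(rule, ctx, sub, revel, rules, refseq)
                if label is not None:
                    return ClassifiedVariant(
                        record, category, subcategory=label,
                        triggering_rule=rule.label, flags=flags, **base,
                    )

    in_vps10p = any(ctx.segment == "VPS10p" for ctx in contexts)
    if revel is None:
        if revel_needed or in_vps10p:
            flags.add("revel_unannotated")
        return ClassifiedVariant(record, Category.NPV, flags=flags, **base)
    if revel >= rules.revel_threshold and not in_vps10p:
        return ClassifiedVariant(
            record, Category.LPV, subcategory="revel_high",
            triggering_rule="revel_threshold", flags=flags, **base,
        )
    return ClassifiedVariant(record, Category.NPV, flags=flags, **base)


def classify_all(
    cohort: Cohort,
    arch: Optional[DomainArchitecture] = None,
    rules: Optional[PriorityRuleSet] = None,
) -> list[ClassifiedVariant]:
    """Classify every variant in the cohort (defaults: packaged config)."""
    arch = arch if arch is not None else load_architecture()
    rules = rules if rules is not None else load_ruleset()
    rules.validate_against(arch)
    return [classify_variant(rec, arch, rules, cohort) for rec in cohort.variants]


# -- carrier grouping ----------------------------------------------------


def assign_carrier_category(
    individual: CohortIndividual, classified: Sequence[ClassifiedVariant]
) -> Category:
    """Group a multi-variant carrier by their highest-priority variant.

    EXCLUDED variants never contribute; an individual carrying none of the
    analyzed variants is WT.
    """
    cats = [c.category for c in classified if c.category is not Category.EXCLUDED]
    if not cats:
        return Category.WT
    return max(cats)


def carrier_categories(
    cohort: Cohort,
    classified: Sequence[ClassifiedVariant],
    dosage_threshold: float = 0.5,
) -> dict[str, Category]:
    """Per-individual category map over the whole cohort."""
    carried: dict[str, list[ClassifiedVariant]] = {i.id: [] for i in cohort.individuals}
    for cv in classified:
        for ind in carrier_set(cv.record, dosage_threshold):
            carried[ind].append(cv)
    return {
        ind_id: assign_carrier_category(cohort.individual(ind_id), cvs)
        for ind_id, cvs in carried.items()
    }
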