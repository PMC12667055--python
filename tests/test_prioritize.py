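"""DMDM classification: PTV logic, cysteine rules, decision order, carrier
grouping, and agreement with an independent brute-force rule evaluator."""

import pytest

from sorlvar.domain import locate_residue
from sorlvar.ingest import (
    ChangeKind,
    Cohort,
    CohortIndividual,
    ProteinChange,
    VariantRecord,
)
from sorlvar.prioritize import (
    Category,
    ClassifiedVariant,
    assign_carrier_category,
    carrier_categories,
    classify_variant,
    cysteine_change,
    is_ptv,
    load_ruleset,
)


@pytest.fixture(scope="module")
def tiny_cohort():
    inds = [CohortIndividual(f"I{k}", "control", 70.0) for k in range(100)]
    return Cohort(individuals=inds)


def _rec(hgvs=None, consequence=None, exon=None, revel=None, loftee=0,
         splice=None, maf=1e-5):
    return VariantRecord(
        variant_id="11:121300000:A>G",
        hgvs_p=ProteinChange(*hgvs) if hgvs else None,
        consequence=consequence,
        exon=exon,
        revel=revel,
        loftee_flag=loftee,
        splice_score=splice,
        gnomad_nonneuro_popmax_maf=maf,
    )


class TestIsPtv:
    def test_loftee_flagged_nonsense(self, rules):
        rec = _rec(("R", 744, "*", ChangeKind.NONSENSE), loftee=1)
        assert is_ptv(rec, rules) == (True, False)

    def test_exon48_nonsense_rescued_without_loftee(self, rules):
        rec = _rec(("R", 2200, "*", ChangeKind.NONSENSE), exon=48, loftee=0)
        assert is_ptv(rec, rules) == (True, False)

    def test_high_scoring_splice_needs_review_not_promotion(self, rules):
        rec = _rec(consequence="splice_donor_variant", loftee=0, splice=0.9)
        assert is_ptv(rec, rules) == (False, True)

    def test_missense_is_not_ptv(self, rules):
        rec = _rec(("Y", 391, "C", ChangeKind.MISSENSE))
        assert is_ptv(rec, rules) == (False, False)


class TestCysteineChange:
    def test_gain(self):
        assert cysteine_change(None, ("Y", 391, "C")) == "gain"

    def test_loss(self):
        assert cysteine_change(None, ("C", 467, "Y")) == "loss"

    def test_neither(self):
        assert cysteine_change(None, ("D", 1108, "N")) is None

    def test_reference_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch at residue 3"):
            cysteine_change("AAY", ("C", 3, "S"))

    def test_reference_checked_when_present(self):
        assert cysteine_change("AAC", ("C", 3, "S")) == "loss"


@pytest.mark.parametrize(
    "hgvs, revel, maf, category, rule",
    [
        # cysteine gained in VPS10p loop L1
        (("Y", 391, "C"), 0.2, 1e-5, Category.HPV, "L1_cysteine"),
        # calcium cage of the 1st CR domain
        (("D", 1108, "N"), 0.4, 1e-5, Category.HPV, "CR_calcium_cage"),
        # tyrosine corner of the 3rd 3Fn domain
        (("Y", 1816, "C"), 0.3, 1e-5, Category.HPV, "3Fn_conserved"),
        # CR-cluster cysteine loss (odd number of cysteines)
        (("C", 1453, "F"), 0.6, 1e-5, Category.HPV, "CR_cysteine"),
        # conserved YWTD-blade arginine site (blade 5 position 38)
        (("R", 953, "H"), 0.9, 1e-5, Category.HPV, "YWTD_partly_conserved"),
        # VPS10p missense above the REVEL gate
        (("S", 564, "G"), 0.8, 1e-5, Category.HPV, "VPS10p_revel"),
        # 3Fn moderate-priority proline (position 6 of 3Fn2: 1637+5)
        (("P", 1642, "L"), 0.2, 1e-5, Category.MPV, "3Fn_proline"),
        # common variant routed to the less-rare analysis
        (("A", 528, "T"), 0.7, 0.036, Category.LESS_RARE, None),
        # high REVEL outside VPS10p and outside all fixed rules
        (("E", 1500, "K"), 0.8, 1e-5, Category.LPV, "revel_threshold"),
        # low REVEL, no rule
        (("E", 1500, "K"), 0.1, 1e-5, Category.NPV, None),
        # VPS10p missense below the gate stays NPV (LPV excludes VPS10p)
        (("G", 300, "A"), 0.3, 1e-5, Category.NPV, None),
    ],
)
def test_classification_decision_order(arch_noseq, rules, tiny_cohort,
                                       hgvs, revel, maf, category, rule):
    ref, pos, alt = hgvs
    rec = _rec((ref, pos, alt, ChangeKind.MISSENSE), revel=revel, maf=maf)
    cv = classify_variant(rec, arch_noseq, rules, tiny_cohort)
    assert cv.category is category
    assert cv.triggering_rule == rule


def test_exclusion_region_wins_over_everything(arch_noseq, rules, tiny_cohort):
    rec = _rec(("G", 50, "C", ChangeKind.MISSENSE), revel=0.99, exon=1)
    cv = classify_variant(rec, arch_noseq, rules, tiny_cohort)
    assert cv.category is Category.EXCLUDED


def test_splice_review_flag_propagates(arch_noseq, rules, tiny_cohort):
    rec = _rec(consequence="splice_region_variant", loftee=0, splice=0.8)
    cv = classify_variant(rec, arch_noseq, rules, tiny_cohort)
    assert cv.category is Category.NPV
    assert cv.needs_manual_review
    assert "splice_review" in cv.flags


def test_missing_revel_in_vps10p_conservative_npv(arch_noseq, rules, tiny_cohort):
    rec = _rec(("G", 300, "A", ChangeKind.MISSENSE), revel=None)
    cv = classify_variant(rec, arch_noseq, rules, tiny_cohort)
    assert cv.category is Category.NPV
    assert "revel_unannotated" in cv.flags


def test_rule_provenance_nonempty_for_priorities(small_cohort, arch, rules):
    from sorlvar.prioritize import classify_all

    cohort, _ = small_cohort
    for cv in classify_all(cohort, arch, rules):
        if cv.category in (Category.HPV, Category.MPV):
            assert cv.triggering_rule


def test_removing_triggering_rule_demotes_variant(small_cohort, arch, rules):
    """Mutation test: each HPV/MPV must lose its category (or fire a
    different rule) when its triggering rule is deleted from the rule set."""
    import dataclasses

    from sorlvar.prioritize import classify_all, classify_variant

    cohort, _ = small_cohort
    classified = [cv for cv in classify_all(cohort, arch, rules)
                  if cv.category in (Category.HPV, Category.MPV)]
    assert classified
    for cv in classified[:40]:
        mutated = dataclasses.replace(
            rules,
            high_rules=[r for r in rules.high_rules
                        if r.label != cv.triggering_rule],
            moderate_rules=[r for r in rules.moderate_rules
                            if r.label != cv.triggering_rule],
        )
        cv2 = classify_variant(cv.record, arch, mutated, cohort)
        assert (cv2.category < cv.category
                or cv2.triggering_rule != cv.triggering_rule)


class TestAssignCarrierCategory:
    def _cv(self, cat):
        rec = _rec(("Y", 391, "C", ChangeKind.MISSENSE))
        return ClassifiedVariant(rec, cat)

    def test_ptv_beats_hpv(self):
        ind = CohortIndividual("A", "case", 46.0)
        got = assign_carrier_category(
            ind, [self._cv(Category.HPV), self._cv(Category.PTV)]
        )
        assert got is Category.PTV

    def test_lpv_beats_npv(self):
        ind = CohortIndividual("A", "case", 60.0)
        got = assign_carrier_category(
            ind, [self._cv(Category.NPV), self._cv(Category.LPV)]
        )
        assert got is Category.LPV

    def test_non_carrier_is_wild_type(self):
        ind = CohortIndividual("A", "control", 70.0)
        assert assign_carrier_category(ind, []) is Category.WT

    def test_excluded_variants_do_not_count(self):
        ind = CohortIndividual("A", "case", 60.0)
        assert assign_carrier_category(ind, [self._cv(Category.EXCLUDED)]) \
            is Category.WT


def test_partition_every_variant_gets_one_category(small_cohort, arch, rules):
    from collections import Counter

    from sorlvar.prioritize import classify_all

    cohort, _ = small_cohort
    classified = classify_all(cohort, arch, rules)
    assert len(classified) == len(cohort.variants)
    counts = Counter(cv.category for cv in classified)
    assert sum(counts.values()) == len(cohort.variants)


def test_classification_is_deterministic(small_cohort, arch, rules):
    from sorlvar.prioritize import classify_all

    cohort, _ = small_cohort
    first = [(c.category, c.triggering_rule) for c in classify_all(cohort, arch, rules)]
    second = [(c.category, c.triggering_rule) for c in classify_all(cohort, arch, rules)]
    assert first == second


# -- independent oracle ---------------------------------------------------


def _oracle_classify(rec, arch, rules, cohort):
    """Brute-force re-evaluation of the written rule list, implemented
    independently of classify_variant's control flow."""
    from sorlvar.ingest import carrier_set

    if cohort.is_excluded(rec):
        return Category.EXCLUDED
    maf = rec.gnomad_nonneuro_popmax_maf
    if maf is None:
        maf = len(carrier_set(rec)) / len(cohort)
    if maf >= rules.maf_threshold:
        return Category.LESS_RARE
    if rec.loftee_flag == 1 or (
        rec.change_kind in (ChangeKind.NONSENSE, ChangeKind.FRAMESHIFT)
        and rec.exon in rules.ptv_exon_rescue
    ):
        return Category.PTV
    if rec.hgvs_p is None or rec.hgvs_p.kind is not ChangeKind.MISSENSE:
        return Category.NPV

    fired = {"high": False, "moderate": False}
    segments = set()
    for ref, pos, alt in rec.hgvs_p.substitutions():
        ctx = locate_residue(arch, pos)
        segments.add(ctx.segment)
        for rule in rules.high_rules + rules.moderate_rules:
            kind, _, name = rule.scope.partition(":")
            in_scope = (ctx.segment == name if kind == "segment"
                        else ctx.repeat_class == name
                        and (rule.positions == "any"
                             or ctx.repeat_position in tuple(rule.positions)))
            if not in_scope:
                continue
            hit = False
            if rule.trigger == "fixed_position":
                hit = True
            elif rule.trigger == "cysteine_gain_or_loss":
                hit = (alt == "C") != (ref == "C")
            elif rule.trigger == "revel_at_least":
                hit = rec.revel is not None and rec.revel >= rules.revel_threshold
            if hit:
                fired[rule.priority] = True
    if fired["high"]:
        return Category.HPV
    if fired["moderate"]:
        return Category.MPV
    if (rec.revel is not None and rec.revel >= rules.revel_threshold
            and "VPS10p" not in segments):
        return Category.LPV
    return Category.NPV


def test_classifier_equals_brute_force_oracle(small_cohort, arch, rules):
    from sorlvar.prioritize import classify_all

    cohort, _ = small_cohort
    classified = classify_all(cohort, arch, rules)
    for cv in classified:
        assert cv.category is _oracle_classify(cv.record, arch, rules, cohort), \
            cv.record.variant_id


def test_carrier_categories_match_individual_truth(small_cohort, arch, rules):
    from sorlvar.prioritize import classify_all

    cohort, truth = small_cohort
    cats = carrier_categories(cohort, classify_all(cohort, arch, rules))
    assert cats == truth.individual_category
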