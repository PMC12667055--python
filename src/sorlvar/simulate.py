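"""Synthetic variant tables and case/control cohorts.

The generator emulates the statistical structure the analysis assumes — a
large assembled case/control sample with rare variant categories of known
odds ratios, APOE-e4 as a strong additive risk factor and onset-age modifier,
and a variant list spanning every domain-rule class with known truth
categories — so classification, burden and AAO stages are testable end to end
without any protected data.

Disease status follows a logistic model on the logit scale:

    logit P(case) = b0 + log(OR_category) + e4_count * log(OR_APOE)

with b0 calibrated so the expected case fraction matches the requested cohort
composition.  Case ages at onset are truncated normal (bounds 30–105):
wt_aao_median + category shift + e4_count * apoe_aao_shift + noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .domain import DomainArchitecture, locate_residue
from .ingest import (
    ChangeKind,
    Cohort,
    CohortIndividual,
    ProteinChange,
    VariantRecord,
)
from .prioritize import Category, PriorityRuleSet

__all__ = [
    "SimulationParams",
    "TruthLabels",
    "synthetic_reference_sequence",
    "simulate_variant_table",
    "simulate_cohort",
]

AA_NO_C = "ADEFGHIKLMNPQRSTVWY"

#: Within-repeat cysteine positions stamped onto the synthetic reference.
CR_CYS_POSITIONS = (4, 10, 16, 23, 30, 34)
CR_FIXED_POSITIONS = (37, 41, 44, 47, 48)
FN3_FIXED_POSITIONS = (6, 7, 25, 36, 41, 77, 79, 83, 96)
YWTD_FIXED_POSITIONS = (9, 17, 18, 19, 20, 29, 35, 38)


@dataclass
class SimulationParams:
    """Generator knobs; defaults mirror the assembled study's structure:
    ~19k cases (EOAD fraction ~0.32) vs ~22k controls, per-category control
    carrier frequencies and odds ratios at the published magnitudes, wild-type
    median onset 72 y with 10–90% spread of ~30 y, PTV/HPV onset shifts of
    −10/−8 y, and a 3-fold per-allele APOE-e4 risk with ~−5.5 y onset shift.
    """

    n_cases: int = 18959
    n_controls: int = 21893
    eoad_fraction: float = 0.325  # consistency target, see methods note
    category_control_prevalence: dict = field(default_factory=lambda: {
        Category.PTV: 6 / 21893,
        Category.HPV: 29 / 21893,
        Category.MPV: 61 / 21893,
        Category.LPV: 85 / 21893,
        Category.NPV: 312 / 21893,
        Category.LESS_RARE: 0.10,
    })
    category_or: dict = field(default_factory=lambda: {
        Category.PTV: 17.0,
        Category.HPV: 6.0,
        Category.MPV: 1.5,
        Category.LPV: 1.2,
        Category.NPV: 1.1,
        Category.LESS_RARE: 1.0,
    })
    wt_aao_median: float = 72.0
    aao_shift: dict = field(default_factory=lambda: {
        Category.PTV: -10.0,
        Category.HPV: -8.0,
        Category.MPV: 0.0,
        Category.LPV: 0.0,
        Category.NPV: 0.0,
        Category.LESS_RARE: 0.0,
    })
    aao_dispersion: float = 12.0
    aao_bounds: tuple[float, float] = (30.0, 105.0)
    control_age_mean: float = 71.0
    control_age_sd: float = 16.0
    control_age_bounds: tuple[float, float] = (40.0, 105.0)
    apoe_e4_freq: float = 0.15
    apoe_e2_freq: float = 0.06
    apoe_per_allele_or: float = 3.0
    apoe_aao_shift: float = -5.5
    apoe_missing_frac_controls: float = 0.0
    pc_noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("cohort sizes must be positive")
        for cat, f in self.category_control_prevalence.items():
            if not (0.0 < f < 1.0):
                raise ValueError(f"prevalence for {cat} out of (0,1): {f}")
        for cat, orr in self.category_or.items():
            if not orr > 0:
                raise ValueError(f"odds ratio for {cat} must be > 0: {orr}")


@dataclass
class TruthLabels:
    """Ground truth of a simulation: per-variant category and rule, and (after
    cohort simulation) per-individual carrier category."""

    variant_category: dict[str, Category] = field(default_factory=dict)
    variant_rule: dict[str, Optional[str]] = field(default_factory=dict)
    individual_category: dict[str, Category] = field(default_factory=dict)


# -- reference sequence --------------------------------------------------


def synthetic_reference_sequence(
    arch: DomainArchitecture, seed: int = 0
) -> str:
    """A random amino-acid sequence carrying the residue identities the
    domain rules presuppose (labelled synthetic: it is not the real protein).

    Cysteines appear only at designated repeat positions (CR disulfide
    pattern, 10CC/EGF/L1/L2 cysteines), calcium cages are D/D/D/E, the YWTD
    tetrad spells Y/W/T/D, and the 3Fn conserved residues (tyrosine corner
    L/P/Y, glycines, prolines, core W/Y) are in place.
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(AA_NO_C), size=arch.protein_length))

    def put(pos: int, aa: str) -> None:
        if 1 <= pos <= arch.protein_length:
            seq[pos - 1] = aa

    for rep in arch.repeats:
        length = rep.end - rep.start + 1

        def putr(p: int, aa: str) -> None:
            if p <= length:
                put(rep.start + p - 1, aa)

        if rep.repeat_class == "CR":
            for p, aa in zip((37, 41, 47, 48), "DDDE"):
                putr(p, aa)
            putr(44, "D")
            for p in CR_CYS_POSITIONS:
                putr(p, "C")
        elif rep.repeat_class == "3Fn":
            putr(25, "W")
            putr(36, "G")
            putr(41, "Y")
            putr(77, "L")
            putr(79, "P")
            putr(83, "Y")
            putr(96, "G")
            putr(6, "P")
            putr(7, "P")
        elif rep.repeat_class == "YWTD_blade":
            for p, aa in zip((17, 18, 19, 20), "YWTD"):
                putr(p, aa)
        elif rep.repeat_class in ("L1_loop", "L2_loop"):
            putr(5, "C")
            putr(15, "C")
    seg = {s.name: s for s in arch.segments}
    for k in range(10):  # 10CC cysteines
        put(seg["10CC"].start + 13 * k, "C")
    for k in range(8):  # EGF cysteines
        put(seg["EGF"].start + 7 * k, "C")
    return "".join(seq)


# -- exon model ----------------------------------------------------------

# Approximate residue->exon map for the 48-exon gene: exon 1 covers residues
# 1-95, exon 22 the EGF domain, exons 23-33 one CR repeat each, exon 48 the
# C-terminal tail; remaining exons are interpolated.
_EXON_STARTS = (
    [1]                                        # exon 1
    + [96 + round(918 * k / 20) for k in range(20)]   # exons 2-21
    + [1014]                                   # exon 22
    + [1075 + round(476 * k / 11) for k in range(11)]  # exons 23-33
    + [1551 + round(589 * k / 14) for k in range(14)]  # exons 34-47
    + [2140]                                   # exon 48
)


def exon_of_residue(position: int) -> int:
    return int(np.searchsorted(_EXON_STARTS, position, side="right"))


# -- variant table -------------------------------------------------------

RARE_MAF = 1e-5
LESS_RARE_MAF = 0.02


def _mk_missense(vid, ref, pos, alt, revel, maf=RARE_MAF, **kw) -> VariantRecord:
    return VariantRecord(
        variant_id=vid,
        hgvs_p=ProteinChange(ref, pos, alt, ChangeKind.MISSENSE),
        consequence="missense_variant",
        exon=exon_of_residue(pos),
        revel=revel,
        gnomad_nonneuro_popmax_maf=maf,
        **kw,
    )


class CoverageError(ValueError):
    """n_variants too small for the requested rule-class coverage."""

    def __init__(self, uncovered: Sequence[str]):
        self.uncovered = list(uncovered)
        super().__init__(
            "n_variants too small; uncovered classes: " + ", ".join(self.uncovered)
        )


def simulate_variant_table(
    arch: DomainArchitecture,
    rules: PriorityRuleSet,
    n_variants: int = 250,
    seed: int = 0,
) -> tuple[list[VariantRecord], TruthLabels]:
    """Generate a variant table covering every rule class, with truth labels.

    Requires a reference sequence on the architecture (use
    :func:`synthetic_reference_sequence`).  Emits at least one variant per
    rule class — calcium cage, Asx-turn, ONC gain/loss, 10CC/EGF/L1/L2
    cysteines, YWTD motif and conserved positions, 3Fn tyrosine
    corner/glycines/prolines, the VPS10p/10CC REVEL gates, exon-48 rescued
    PTVs, splice-review cases, a less-rare variant and an excluded exon-1
    variant — then fills with LPV/NPV background to ``n_variants``.
    """
    if arch.reference_sequence is None:
        raise ValueError("architecture needs a reference sequence")
    refseq = arch.reference_sequence
    rng = np.random.default_rng(seed)
    records: list[VariantRecord] = []
    truth = TruthLabels()
    counter = {"n": 0}

    def vid() -> str:
        counter["n"] += 1
        # synthetic genomic keys on the GRCh37 SORL1 locus (chr 11)
        return f"11:{121300000 + 100 * counter['n']}:A>G"

    def alt_for(pos: int, allow_c: bool = False) -> str:
        ref = refseq[pos - 1]
        pool = [a for a in (AA_NO_C + ("C" if allow_c else "")) if a != ref]
        return str(rng.choice(pool))

    def add(rec: VariantRecord, category: Category, rule: Optional[str]) -> None:
        records.append(rec)
        truth.variant_category[rec.variant_id] = category
        truth.variant_rule[rec.variant_id] = rule

    def revel_any() -> float:
        return float(np.round(rng.uniform(0.0, 1.0), 3))

    def revel_ge(thr: float) -> float:
        return float(np.round(rng.uniform(thr, 1.0), 3))

    def revel_lt(thr: float) -> float:
        return float(np.round(rng.uniform(0.0, thr - 1e-3), 3))

    def repeat_positions(cls: str, within: Sequence[int]) -> list[int]:
        out = []
        for rep in arch.repeats:
            if rep.repeat_class != cls:
                continue
            for p in within:
                if p <= rep.end - rep.start + 1:
                    out.append(rep.start + p - 1)
        return out

    thr = rules.revel_threshold

    # --- fixed-position high rules (one per rule class, positions varied)
    for gpos in rng.choice(repeat_positions("CR", (37, 41, 47, 48)), 4, replace=False):
        add(_mk_missense(vid(), refseq[gpos - 1], int(gpos), alt_for(int(gpos)),
                         revel_any()), Category.HPV, "CR_calcium_cage")
    gpos = int(rng.choice(repeat_positions("CR", (44,))))
    add(_mk_missense(vid(), refseq[gpos - 1], gpos, alt_for(gpos), revel_any()),
        Category.HPV, "CR_asx_turn")
    for p_set, rule in (((17, 18, 19, 20), "YWTD_motif"),
                        ((29, 35), "YWTD_conserved"),
                        ((9, 38), "YWTD_partly_conserved")):
        for gpos in rng.choice(repeat_positions("YWTD_blade", p_set),
                               2, replace=False):
            add(_mk_missense(vid(), refseq[gpos - 1], int(gpos),
                             alt_for(int(gpos)), revel_any()),
                Category.HPV, rule)
    for p_set, rule in (((36, 96), "3Fn_glycine"),
                        ((25, 41, 77, 83), "3Fn_conserved"),
                        ((79,), "3Fn_tyrosine_corner_proline")):
        for gpos in rng.choice(repeat_positions("3Fn", p_set),
                               min(2, len(p_set)), replace=False):
            add(_mk_missense(vid(), refseq[gpos - 1], int(gpos),
                             alt_for(int(gpos)), revel_any()),
                Category.HPV, rule)

    # --- cysteine gains and losses per scope
    def cluster_positions(predicate) -> np.ndarray:
        return np.array(
            [p for p in range(1, arch.protein_length + 1) if predicate(p)]
        )

    def cys_safe_nonrule(p: int, segment: str) -> bool:
        ctx = locate_residue(arch, p)
        if ctx.segment != segment or refseq[p - 1] == "C":
            return False
        if ctx.repeat_class == "CR" and ctx.repeat_position in CR_FIXED_POSITIONS:
            return False
        if ctx.repeat_class == "3Fn" and ctx.repeat_position in FN3_FIXED_POSITIONS:
            return False
        return True

    for segment, rule in (("CR_cluster", "CR_cysteine"),
                          ("10CC", "10CC_cysteine"),
                          ("EGF", "EGF_cysteine")):
        gpos = int(rng.choice(cluster_positions(
            lambda p, s=segment: cys_safe_nonrule(p, s))))
        add(_mk_missense(vid(), refseq[gpos - 1], gpos, "C", revel_lt(thr)),
            Category.HPV, rule)  # gain
        cys_at = cluster_positions(
            lambda p, s=segment: locate_residue(arch, p).segment == s
            and refseq[p - 1] == "C"
        )
        gpos = int(rng.choice(cys_at))
        add(_mk_missense(vid(), "C", gpos, alt_for(gpos), revel_any()),
            Category.HPV, rule)  # loss
    for cls, rule in (("L1_loop", "L1_cysteine"), ("L2_loop", "L2_cysteine")):
        rep = next(r for r in arch.repeats if r.repeat_class == cls)
        non_c = [p for p in range(rep.start, rep.end + 1) if refseq[p - 1] != "C"]
        gpos = int(rng.choice(non_c))
        add(_mk_missense(vid(), refseq[gpos - 1], gpos, "C", revel_lt(thr)),
            Category.HPV, rule)

    # --- REVEL-gated HPVs in VPS10p / 10CC
    def plain_positions(segment: str) -> list[int]:
        return [
            p for p in range(1, arch.protein_length + 1)
            if cys_safe_nonrule(p, segment)
            and locate_residue(arch, p).repeat_class is None
        ]

    for segment, rule in (("VPS10p", "VPS10p_revel"), ("10CC", "10CC_revel")):
        for gpos in rng.choice(plain_positions(segment), 2, replace=False):
            add(_mk_missense(vid(), refseq[gpos - 1], int(gpos),
                             alt_for(int(gpos)), revel_ge(thr)),
                Category.HPV, rule)

    # --- moderate rules
    for gpos in rng.choice(repeat_positions("3Fn", (6, 7)), 2, replace=False):
        add(_mk_missense(vid(), refseq[gpos - 1], int(gpos), alt_for(int(gpos)),
                         revel_any()), Category.MPV, "3Fn_proline")

    # --- PTVs
    for gpos in rng.integers(100, 2100, size=3):
        gpos = int(gpos)
        add(VariantRecord(vid(), hgvs_p=ProteinChange(refseq[gpos - 1], gpos, "*",
                                                      ChangeKind.NONSENSE),
                          consequence="stop_gained", exon=exon_of_residue(gpos),
                          loftee_flag=1, gnomad_nonneuro_popmax_maf=RARE_MAF),
            Category.PTV, None)
    gpos = int(rng.integers(100, 2100))
    add(VariantRecord(vid(), hgvs_p=ProteinChange(refseq[gpos - 1], gpos, refseq[gpos - 1],
                                                  ChangeKind.FRAMESHIFT),
                      consequence="frameshift_variant", exon=exon_of_residue(gpos),
                      loftee_flag=1, gnomad_nonneuro_popmax_maf=RARE_MAF),
        Category.PTV, None)
    add(VariantRecord(vid(), consequence="splice_donor_variant", exon=20,
                      loftee_flag=1, splice_score=0.95,
                      gnomad_nonneuro_popmax_maf=RARE_MAF),
        Category.PTV, None)
    gpos = int(rng.integers(2141, arch.protein_length))  # exon-48 rescue
    add(VariantRecord(vid(), hgvs_p=ProteinChange(refseq[gpos - 1], gpos, "*",
                                                  ChangeKind.NONSENSE),
                      consequence="stop_gained", exon=48, loftee_flag=0,
                      gnomad_nonneuro_popmax_maf=RARE_MAF),
        Category.PTV, None)

    # --- residual classes
    add(VariantRecord(vid(), consequence="splice_region_variant", exon=25,
                      loftee_flag=0, splice_score=0.8,
                      gnomad_nonneuro_popmax_maf=RARE_MAF),
        Category.NPV, None)  # needs manual review, not auto-promoted
    gpos = int(rng.choice(plain_positions("VPS10p")))
    add(_mk_missense(vid(), refseq[gpos - 1], gpos, alt_for(gpos), None),
        Category.NPV, None)  # missense with missing REVEL -> conservative NPV
    gpos = int(rng.choice(plain_positions("VPS10p")))
    add(_mk_missense(vid(), refseq[gpos - 1], gpos, alt_for(gpos),
                     revel_ge(thr), maf=LESS_RARE_MAF),
        Category.LESS_RARE, None)
    gpos = int(rng.integers(1, 96))  # exon-1 exclusion region
    add(_mk_missense(vid(), refseq[gpos - 1], gpos, alt_for(gpos), revel_any()),
        Category.EXCLUDED, None)

    if len(records) > n_variants:
        raise CoverageError(
            sorted({truth.variant_rule[r.variant_id] or str(truth.variant_category[r.variant_id])
                    for r in records[n_variants:]})
        )

    # --- LPV / NPV background fill
    def lpv_ok(p: int) -> bool:
        ctx = locate_residue(arch, p)
        if ctx.segment in ("VPS10p", "10CC", "signal_peptide", "pro"):
            return False
        if refseq[p - 1] == "C":
            return False
        if ctx.repeat_class == "CR" and ctx.repeat_position in CR_FIXED_POSITIONS:
            return False
        if ctx.repeat_class == "3Fn" and ctx.repeat_position in FN3_FIXED_POSITIONS:
            return False
        if ctx.repeat_class == "YWTD_blade" and ctx.repeat_position in YWTD_FIXED_POSITIONS:
            return False
        return True

    def npv_ok(p: int) -> bool:
        ctx = locate_residue(arch, p)
        return lpv_ok(p) or (
            ctx.segment in ("VPS10p", "10CC")
            and refseq[p - 1] != "C"
            and ctx.repeat_class is None
        )

    lpv_pool = [p for p in range(96, arch.protein_length + 1) if lpv_ok(p)]
    npv_pool = [p for p in range(96, arch.protein_length + 1) if npv_ok(p)]
    n_fill = n_variants - len(records)
    n_lpv = n_fill // 3
    for gpos in rng.choice(lpv_pool, n_lpv, replace=True):
        add(_mk_missense(vid(), refseq[int(gpos) - 1], int(gpos),
                         alt_for(int(gpos)), revel_ge(thr)),
            Category.LPV, "revel_threshold")
    for gpos in rng.choice(npv_pool, n_fill - n_lpv, replace=True):
        add(_mk_missense(vid(), refseq[int(gpos) - 1], int(gpos),
                         alt_for(int(gpos)), revel_lt(thr)),
            Category.NPV, None)
    return records, truth


# -- cohort --------------------------------------------------------------


def _population_category_probs(
    control_freq: np.ndarray,
    cat_log_or: np.ndarray,
    case_fraction: float,
    e4_freq: float,
    e4_log_or: float,
    n_iter: int = 40,
) -> np.ndarray:
    """Population category-draw probabilities whose *control* composition
    matches ``control_freq`` under the logistic disease model.

    Because high-OR categories are depleted among controls, the population
    prevalence of a category must exceed its control carrier frequency.  The
    joint fixed point in (pi, b0) is solved on expectations over the APOE-e4
    genotype distribution.
    """
    p_e4 = np.array([(1 - e4_freq) ** 2, 2 * e4_freq * (1 - e4_freq),
                     e4_freq ** 2])
    e4_counts = np.array([0.0, 1.0, 2.0])

    def p_case_given(b0: float, log_or: np.ndarray) -> np.ndarray:
        eta = b0 + log_or[:, None] + e4_counts[None, :] * e4_log_or
        return (1.0 / (1.0 + np.exp(-eta))) @ p_e4

    pi = control_freq.copy()
    log_or_all = np.concatenate([cat_log_or, [0.0]])  # + wild-type
    b0 = 0.0
    for _ in range(n_iter):
        weights = np.concatenate([pi, [1.0 - pi.sum()]])

        def overall(b0_):
            return float(p_case_given(b0_, log_or_all) @ weights) - case_fraction

        b0 = optimize.brentq(overall, -30.0, 30.0)
        p_control_cat = 1.0 - p_case_given(b0, cat_log_or)
        pi = control_freq * (1.0 - case_fraction) / p_control_cat
    return pi


def _truncnorm(rng, loc, scale, bounds, size=None):
    a = (bounds[0] - loc) / scale
    b = (bounds[1] - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size,
                               random_state=rng)


def simulate_cohort(
    params: SimulationParams,
    variants: Sequence[VariantRecord],
    labels: TruthLabels,
) -> Cohort:
    """Draw a case/control cohort joined to the given variant table.

    Each individual gets at most one rare-category variant (drawn by the
    per-category control prevalences); case status follows the logistic
    disease model; case AAO and control screening ages follow truncated
    normals.  Carrier dosages are set to 1.  Variants whose truth category is
    EXCLUDED receive a few carriers among otherwise wild-type individuals.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_cases + params.n_controls
    target = params.n_cases / n
    cats = list(params.category_control_prevalence)
    control_freq = np.array([params.category_control_prevalence[c] for c in cats])
    cat_log_or = np.array([np.log(params.category_or.get(c, 1.0)) for c in cats])
    pi = _population_category_probs(
        control_freq, cat_log_or, target,
        params.apoe_e4_freq, np.log(params.apoe_per_allele_or),
    )
    if pi.sum() >= 1.0:
        raise ValueError("category prevalences sum to >= 1")
    probs = np.concatenate([pi, [1.0 - pi.sum()]])
    draw = rng.choice(len(cats) + 1, size=n, p=probs)
    category = np.array([*cats, Category.WT], dtype=object)[draw]

    e4 = rng.binomial(2, params.apoe_e4_freq, size=n)
    e2 = rng.binomial(2, params.apoe_e2_freq, size=n)
    log_or = np.array(
        [np.log(params.category_or.get(c, 1.0)) if c is not Category.WT else 0.0
         for c in category]
    )
    eta_base = log_or + e4 * np.log(params.apoe_per_allele_or)

    def mean_p(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + eta_base)))))

    b0 = optimize.brentq(lambda b: mean_p(b) - target, -30.0, 30.0)
    p_case = 1.0 / (1.0 + np.exp(-(b0 + eta_base)))
    is_case = rng.random(n) < p_case

    shift = np.array(
        [params.aao_shift.get(c, 0.0) if c is not Category.WT else 0.0
         for c in category]
    )
    loc = params.wt_aao_median + shift + e4 * params.apoe_aao_shift
    aao = _truncnorm(rng, loc, params.aao_dispersion, params.aao_bounds, size=n)
    screening_age = _truncnorm(
        rng, params.control_age_mean, params.control_age_sd,
        params.control_age_bounds, size=n,
    )
    age = np.where(is_case, aao, screening_age)
    pcs = rng.normal(0.0, params.pc_noise_scale, size=(n, 6))
    apoe_missing = (~is_case) & (
        rng.random(n) < params.apoe_missing_frac_controls
    )

    ids = np.array([f"I{k:06d}" for k in range(n)])
    individuals = [
        CohortIndividual(
            id=ids[k],
            status="case" if is_case[k] else "control",
            aao_or_age=float(np.round(age[k], 1)),
            apoe_e4_count=None if apoe_missing[k] else int(e4[k]),
            apoe_e2_count=None if apoe_missing[k] else int(e2[k]),
            pcs=tuple(np.round(pcs[k], 4)),
            cohort_label="synthetic",
        )
        for k in range(n)
    ]

    # join carriers: one variant of the individual's category, chosen uniformly
    by_cat: dict[Category, list[VariantRecord]] = {}
    for rec in variants:
        by_cat.setdefault(labels.variant_category[rec.variant_id], []).append(rec)
    carriers: dict[str, dict[str, float]] = {rec.variant_id: {} for rec in variants}
    for k in range(n):
        cat = category[k]
        if cat is Category.WT:
            continue
        pool = by_cat.get(cat)
        if not pool:
            raise ValueError(f"no variants with truth category {cat}")
        rec = pool[int(rng.integers(len(pool)))]
        carriers[rec.variant_id][ids[k]] = 1.0
        labels.individual_category[ids[k]] = cat
    for k in range(n):
        if ids[k] not in labels.individual_category:
            labels.individual_category[ids[k]] = Category.WT
    # excluded-region variants: carriers among wild-type individuals only
    wt_ids = [ids[k] for k in range(n) if category[k] is Category.WT]
    for rec in by_cat.get(Category.EXCLUDED, []):
        for ind in rng.choice(wt_ids, size=3, replace=False):
            carriers[rec.variant_id][str(ind)] = 1.0

    out_variants = [
        replace_carriers(rec, carriers[rec.variant_id]) for rec in variants
    ]
    cohort = Cohort(individuals=individuals, variants=out_variants)

    realized_eoad = float(np.mean(age[is_case] < 65.0))
    if abs(realized_eoad - params.eoad_fraction) > 0.15:
        warnings.warn(
            f"realized EOAD fraction {realized_eoad:.2f} far from declared "
            f"{params.eoad_fraction:.2f}; check the AAO model parameters"
        )
    return cohort


def replace_carriers(rec: VariantRecord, carriers: dict[str, float]) -> VariantRecord:
    return replace(rec, carriers=dict(carriers), flags=set(rec.flags))
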