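"""Odds ratios, Fisher exact p-values, Bonferroni, stratified burden scans,
and covariate-adjusted logistic contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from sorlvar.association import (
    Table2x2,
    adjusted_burden,
    apoe_interaction_lrt,
    bonferroni,
    build_table,
    burden_scan,
    default_strata,
    fisher_p,
    odds_ratio_wald,
)
from sorlvar.ingest import Cohort, CohortIndividual
from sorlvar.prioritize import Category, carrier_categories, classify_all


class TestOddsRatioWald:
    def test_reproduces_ptv_risk_estimate(self):
        o = odds_ratio_wald(Table2x2(89, 18870, 6, 21887))
        assert round(o.odds_ratio, 1) == 17.2
        assert round(o.ci_low, 1) == 7.5
        assert round(o.ci_high, 1) == 39.3

    def test_symmetric_table_is_one(self):
        o = odds_ratio_wald(Table2x2(10, 10, 10, 10))
        assert o.odds_ratio == pytest.approx(1.0)
        assert o.ci_low < 1.0 < o.ci_high

    def test_zero_cell_is_na(self):
        assert odds_ratio_wald(Table2x2(0, 100, 5, 95)).is_na

    def test_haldane_anscombe_optional(self):
        o = odds_ratio_wald(Table2x2(0, 100, 5, 95), haldane_anscombe=True)
        assert o.odds_ratio == pytest.approx((0.5 * 95.5) / (100.5 * 5.5))


_cell = st.integers(min_value=1, max_value=200)


@given(a=_cell, b=_cell, c=_cell, d=_cell)
def test_or_transposition_and_label_flip_symmetry(a, b, c, d):
    o = odds_ratio_wald(Table2x2(a, b, c, d)).odds_ratio
    transposed = odds_ratio_wald(Table2x2(a, c, b, d)).odds_ratio
    flipped = odds_ratio_wald(Table2x2(c, d, a, b)).odds_ratio
    assert transposed == pytest.approx(o)
    assert flipped == pytest.approx(1.0 / o)


class TestFisher:
    def test_disjoint_small_table(self):
        # exhaustive hypergeometric sum: 2 of 252 tables are as extreme
        assert fisher_p(Table2x2(5, 0, 0, 5)) == pytest.approx(
            2 / math.comb(10, 5), abs=1e-15
        )

    def test_balanced_table_is_one(self):
        assert fisher_p(Table2x2(1, 1, 1, 1)) == 1.0

    def test_large_table_tail_bound(self):
        assert fisher_p(Table2x2(89, 18870, 6, 21887)) < 1e-20

    @given(a=st.integers(0, 25), b=st.integers(0, 25),
           c=st.integers(0, 25), d=st.integers(0, 25))
    def test_matches_scipy_cross_check(self, a, b, c, d):
        ours = fisher_p(Table2x2(a, b, c, d))
        _, theirs = stats.fisher_exact([[a, b], [c, d]])
        assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-12)

    def test_large_support_path_matches_scipy(self):
        t = Table2x2(5200, 4800, 4900, 5100)
        _, theirs = stats.fisher_exact([[5200, 4800], [4900, 5100]])
        assert fisher_p(t) == pytest.approx(theirs, rel=1e-9)


class TestBonferroni:
    def test_scales_by_family(self):
        assert bonferroni([0.01], 5) == [0.05]

    def test_caps_at_one(self):
        assert bonferroni([0.5], 3) == [1.0]

    def test_single_test_identity(self):
        assert bonferroni([0.2], 1) == [0.2]

    def test_family_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], 1)


@pytest.fixture(scope="module")
def classified_cohort(small_cohort, arch, rules):
    cohort, _ = small_cohort
    cats = carrier_categories(cohort, classify_all(cohort, arch, rules))
    return cohort, cats


class TestBuildTableAndScan:
    def test_stratification_consistency(self, classified_cohort):
        cohort, cats = classified_cohort
        s_all, s_eoad, s_load = default_strata()
        for label in (Category.PTV, Category.HPV, Category.NPV):
            t_all = build_table(cohort, cats, label, s_all)
            t_e = build_table(cohort, cats, label, s_eoad)
            t_l = build_table(cohort, cats, label, s_load)
            assert t_all.case_carriers == t_e.case_carriers + t_l.case_carriers
            # controls are never stratified
            assert t_all.control_carriers == t_e.control_carriers \
                == t_l.control_carriers

    def test_scan_emits_three_strata_per_label(self, classified_cohort):
        cohort, cats = classified_cohort
        results = burden_scan(cohort, cats, labels=[Category.HPV, Category.NPV])
        assert len(results) == 6
        assert {r.stratum for r in results} == {"ALL", "EOAD", "LOAD"}
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_fisher * 6))

    def test_zero_carrier_label_gives_na_or(self, classified_cohort):
        cohort, cats = classified_cohort
        results = burden_scan(cohort, cats, labels=["no_such_label"])
        for r in results:
            assert r.odds_ratio is None
            assert r.table.case_carriers == 0

    def test_bonferroni_family_override(self, classified_cohort):
        cohort, cats = classified_cohort
        results = burden_scan(cohort, cats, labels=[Category.NPV],
                              bonferroni_family=100)
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_fisher * 100))


def _direct_cohort(n, carrier_freq, log_or, seed, e4_beta=0.0):
    """Small cohort built directly from a logistic model (no variant layer)."""
    rng = np.random.default_rng(seed)
    carrier = rng.random(n) < carrier_freq
    e4 = rng.binomial(2, 0.15, size=n)
    eta = -0.2 + log_or * carrier + e4_beta * e4
    case = rng.random(n) < 1 / (1 + np.exp(-eta))
    inds = [
        CohortIndividual(
            f"I{k}", "case" if case[k] else "control",
            aao_or_age=float(rng.uniform(50, 90)),
            apoe_e4_count=int(e4[k]),
            pcs=tuple(rng.normal(0, 1, 6)),
        )
        for k in range(n)
    ]
    cats = {f"I{k}": Category.PTV if carrier[k] else Category.WT
            for k in range(n)}
    return Cohort(individuals=inds), cats


class TestAdjustedBurden:
    def test_recovers_simulated_or_five(self):
        cohort, cats = _direct_cohort(20000, 0.02, math.log(5.0), seed=3)
        res = adjusted_burden(cohort, cats, Category.PTV)
        assert not res["separation"]
        assert res["ci_low"] <= 5.0 <= res["ci_high"]

    def test_null_beta_near_zero(self):
        betas = []
        for seed in range(5):
            cohort, cats = _direct_cohort(8000, 0.05, 0.0, seed=seed)
            betas.append(adjusted_burden(cohort, cats, Category.PTV)["beta"])
        assert abs(np.mean(betas)) < 0.1

    def test_complete_separation_flagged(self):
        rng = np.random.default_rng(0)
        inds, cats = [], {}
        for k in range(400):
            carrier = k < 12
            status = "case" if (carrier or rng.random() < 0.5) else "control"
            inds.append(CohortIndividual(
                f"I{k}", status, 70.0, apoe_e4_count=0,
                pcs=tuple(rng.normal(0, 1, 6)),
            ))
            cats[f"I{k}"] = Category.PTV if carrier else Category.WT
        res = adjusted_burden(Cohort(individuals=inds), cats, Category.PTV)
        assert res["separation"]
        assert res["se"] is None

    def test_no_carriers_is_an_error(self, classified_cohort):
        cohort, cats = classified_cohort
        with pytest.raises(ValueError):
            adjusted_burden(cohort, cats, "no_such_label")


class TestApoeInteractionLrt:
    def test_type_one_error_calibrated_under_additive_model(self):
        rejections = 0
        n_rep = 400
        for seed in range(n_rep):
            cohort, cats = _direct_cohort(
                1500, 0.08, math.log(2.0), seed=seed, e4_beta=math.log(3.0)
            )
            p = apoe_interaction_lrt(cohort, cats, Category.PTV)["p_interaction"]
            rejections += p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_power_exceeds_alpha_under_interaction(self):
        rejections = 0
        rng_or = math.log(2.0)
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(10_000 + seed)
            n = 1500
            carrier = rng.random(n) < 0.08
            e4 = rng.binomial(2, 0.3, size=n)
            eta = -0.2 + rng_or * carrier + math.log(2.0) * e4 \
                + math.log(2.5) * carrier * e4
            case = rng.random(n) < 1 / (1 + np.exp(-eta))
            inds = [CohortIndividual(
                f"I{k}", "case" if case[k] else "control", 70.0,
                apoe_e4_count=int(e4[k]), pcs=tuple(rng.normal(0, 1, 6)))
                for k in range(n)]
            cats = {f"I{k}": Category.PTV if carrier[k] else Category.WT
                    for k in range(n)}
            p = apoe_interaction_lrt(Cohort(individuals=inds), cats,
                                     Category.PTV)["p_interaction"]
            rejections += p < 0.05
        assert rejections / n_rep > 0.3  # clearly above the 5% type-I rate

    def test_zero_carriers_is_an_error(self, classified_cohort):
        cohort, cats = classified_cohort
        with pytest.raises(ValueError):
            apoe_interaction_lrt(cohort, cats, "no_such_label")
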