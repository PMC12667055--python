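"""Published summary counts for the assembled SORL1 case/control study.

These are the printed cohort totals (18,959 AD cases of which 6,155 EOAD;
21,893 controls) and per-category carrier counts from the study's association
table.  They are *inputs*: running :func:`published_burden_table` recomputes
the odds ratios, Wald intervals and Fisher p-values from these counts with the
package's own statistics, which is how the printed results are reproduced
without individual-level data.

Carrier count convention of the source table: the "all" column counts case
*and* control carriers combined, so case carriers = all − controls, and
EOAD + LOAD = case carriers.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .association import Table2x2, fisher_p, odds_ratio_wald

__all__ = [
    "COHORT_TOTALS",
    "CARRIER_COUNTS",
    "published_table",
    "published_burden_table",
]

COHORT_TOTALS = {
    "cases": 18959,
    "eoad_cases": 6155,
    "load_cases": 18959 - 6155,
    "controls": 21893,
}


@dataclass(frozen=True)
class CarrierCounts:
    """all/EOAD/LOAD/control carriers for one variant group."""

    label: str
    all_carriers: int
    eoad_carriers: int
    load_carriers: int
    control_carriers: int

    @property
    def case_carriers(self) -> int:
        return self.all_carriers - self.control_carriers


#: Carrier counts per priority category and per-domain HPV subcategory.
CARRIER_COUNTS: tuple[CarrierCounts, ...] = (
    CarrierCounts("WT", 31324, 4642, 9677, 17005),
    CarrierCounts("NPV", 612, 101, 199, 312),
    CarrierCounts("LPV", 170, 33, 52, 85),
    CarrierCounts("MPV", 141, 20, 60, 61),
    CarrierCounts("HPV", 180, 80, 71, 29),
    CarrierCounts("PTV", 95, 59, 30, 6),
    CarrierCounts("HPV_VPS10p", 43, 22, 16, 5),
    CarrierCounts("HPV_VPS10p_L1L2_cysteines", 18, 8, 8, 2),
    CarrierCounts("HPV_VPS10p_aspbox_revel", 6, 3, 3, 0),
    CarrierCounts("HPV_VPS10p_remaining_revel", 19, 11, 5, 3),
    CarrierCounts("HPV_10CC", 30, 11, 13, 6),
    CarrierCounts("HPV_YWTD", 25, 13, 7, 5),
    CarrierCounts("HPV_YWTD_motif", 8, 6, 2, 0),
    CarrierCounts("HPV_YWTD_conserved", 8, 2, 3, 3),
    CarrierCounts("HPV_YWTD_partly_conserved", 8, 4, 2, 2),
    CarrierCounts("HPV_EGF_cysteines", 2, 1, 0, 1),
    CarrierCounts("HPV_CR", 57, 23, 26, 8),
    CarrierCounts("HPV_CR_calcium_cage", 13, 9, 4, 0),
    CarrierCounts("HPV_CR_cysteines_ONC", 42, 12, 22, 8),
    CarrierCounts("HPV_CR_asx_turn", 2, 2, 0, 0),
    CarrierCounts("HPV_3Fn", 15, 8, 5, 2),
    CarrierCounts("HPV_3Fn_glycines", 2, 1, 1, 0),
    CarrierCounts("HPV_3Fn_prolines", 4, 2, 2, 0),
    CarrierCounts("HPV_3Fn_conserved", 9, 5, 2, 2),
)


def published_table(label: str, stratum: str = "ALL") -> Table2x2:
    """The 2x2 table for one published group and stratum (ALL/EOAD/LOAD)."""
    counts = {c.label: c for c in CARRIER_COUNTS}[label]
    controls = COHORT_TOTALS["controls"]
    if stratum == "ALL":
        a, n_cases = counts.case_carriers, COHORT_TOTALS["cases"]
    elif stratum == "EOAD":
        a, n_cases = counts.eoad_carriers, COHORT_TOTALS["eoad_cases"]
    elif stratum == "LOAD":
        a, n_cases = counts.load_carriers, COHORT_TOTALS["load_cases"]
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    return Table2x2(a, n_cases - a, counts.control_carriers,
                    controls - counts.control_carriers)


def published_burden_table(labels=None) -> pd.DataFrame:
    """Recompute OR (95% CI) and Fisher p per group x stratum from the
    published carrier counts."""
    rows = []
    for counts in CARRIER_COUNTS:
        if labels is not None and counts.label not in labels:
            continue
        for stratum in ("ALL", "EOAD", "LOAD"):
            t = published_table(counts.label, stratum)
            orr = odds_ratio_wald(t)
            rows.append({
                "label": counts.label,
                "stratum": stratum,
                "case_carriers": t.case_carriers,
                "control_carriers": t.control_carriers,
                "odds_ratio": orr.odds_ratio,
                "ci_low": orr.ci_low,
                "ci_high": orr.ci_high,
                "p_fisher": fisher_p(t),
            })
    return pd.DataFrame(rows)
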