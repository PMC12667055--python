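"""Rare-variant burden association: 2x2 odds ratios, Fisher exact tests,
Bonferroni correction, EOAD/LOAD stratification and covariate-adjusted
logistic models.

The point estimate is the sample cross-product odds ratio with a Wald
(log-odds normal approximation) 95% CI — the pairing that reproduces both the
published OR point estimates and their intervals from the published carrier
counts.  Zero-cell tables report NA (a Haldane–Anscombe 0.5 correction is
available behind a flag, off by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import Cohort
from .prioritize import Category, ClassifiedVariant

__all__ = [
    "Table2x2",
    "OddsRatio",
    "BurdenResult",
    "Stratum",
    "default_strata",
    "build_table",
    "odds_ratio_wald",
    "fisher_p",
    "bonferroni",
    "burden_scan",
    "adjusted_burden",
    "apoe_interaction_lrt",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class Table2x2:
    """Carrier counts: a=case carriers, b=case non-carriers,
    c=control carriers, d=control non-carriers."""

    case_carriers: int
    case_noncarriers: int
    control_carriers: int
    control_noncarriers: int

    def __post_init__(self) -> None:
        for v in self.cells:
            if v < 0:
                raise ValueError(f"negative cell count: {self.cells}")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.case_carriers, self.case_noncarriers,
                self.control_carriers, self.control_noncarriers)

    @property
    def total(self) -> int:
        return sum(self.cells)

    def has_zero_cell(self) -> bool:
        return any(v == 0 for v in self.cells)


@dataclass(frozen=True)
class OddsRatio:
    odds_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]

    @property
    def is_na(self) -> bool:
        return self.odds_ratio is None


def odds_ratio_wald(
    table: Table2x2, haldane_anscombe: bool = False, z: float = Z_95
) -> OddsRatio:
    """Cross-product OR with log-scale Wald CI:
    exp(ln OR ± z * sqrt(1/a + 1/b + 1/c + 1/d)).

    Any zero cell yields an NA result unless ``haldane_anscombe`` adds 0.5 to
    every cell.
    """
    a, b, c, d = (float(v) for v in table.cells)
    if table.has_zero_cell():
        if not haldane_anscombe:
            return OddsRatio(None, None, None)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatio(or_, or_ * math.exp(-z * se), or_ * math.exp(z * se))


# -- Fisher's exact test -------------------------------------------------

#: Support sizes up to this bound use exact integer enumeration.
_EXACT_SUPPORT_LIMIT = 1000


def fisher_p(table: Table2x2, alternative: str = "two-sided") -> float:
    """Two-sided Fisher exact p: the probability, under the fixed-margin
    hypergeometric distribution, of any table at most as probable as the one
    observed.

    Small tables use exact integer arithmetic (no floating-point tie
    ambiguity); tables whose hypergeometric support exceeds
    ``_EXACT_SUPPORT_LIMIT`` fall back to scipy.
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    a, b, c, d = table.cells
    r1, c1, n = a + b, a + c, table.total
    if n == 0:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    if hi - lo + 1 > _EXACT_SUPPORT_LIMIT:
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        return float(p)
    n2 = n - r1
    weights = [math.comb(r1, k) * math.comb(n2, c1 - k) for k in range(lo, hi + 1)]
    obs = weights[a - lo]
    num = sum(w for w in weights if w <= obs)
    return float(Fraction(num, math.comb(n, c1)))


def bonferroni(p_values: Sequence[float], family_size: Optional[int] = None) -> list[float]:
    """p_adj = min(1, p * m); m defaults to the number of p-values given."""
    m = len(p_values) if family_size is None else family_size
    if m < len(p_values):
        raise ValueError("family_size smaller than the number of tests")
    return [min(1.0, p * m) for p in p_values]


# -- stratified burden ---------------------------------------------------


@dataclass(frozen=True)
class Stratum:
    """A case stratum; controls are never stratified (always the full set)."""

    name: str
    case_filter: Callable[[float], bool]

    def __repr__(self) -> str:
        return f"Stratum({self.name})"


def default_strata(eoad_boundary: float = 65.0) -> tuple[Stratum, Stratum, Stratum]:
    """ALL / EOAD (onset < boundary) / LOAD (onset >= boundary)."""
    return (
        Stratum("ALL", lambda aao: True),
        Stratum("EOAD", lambda aao, b=eoad_boundary: aao < b),
        Stratum("LOAD", lambda aao, b=eoad_boundary: aao >= b),
    )


def build_table(
    cohort: Cohort,
    carrier_cats: Mapping[str, object],
    label,
    stratum: Stratum,
) -> Table2x2:
    """2x2 table of carrying `label` (a Category or subcategory string) vs
    status, with cases restricted to the stratum and the full control set."""
    cases = [i for i in cohort.cases if stratum.case_filter(i.aao_or_age)]
    if not cases:
        raise ValueError(f"stratum {stratum.name} contains no cases")
    a = sum(1 for i in cases if carrier_cats.get(i.id) == label)
    c = sum(1 for i in cohort.controls if carrier_cats.get(i.id) == label)
    return Table2x2(a, len(cases) - a, c, len(cohort.controls) - c)


@dataclass
class BurdenResult:
    label: str
    stratum: str
    table: Table2x2
    odds_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_fisher: float
    p_adjusted: Optional[float] = None

    def to_dict(self) -> dict:
        t = self.table
        return {
            "label": self.label, "stratum": self.stratum,
            "case_carriers": t.case_carriers,
            "case_noncarriers": t.case_noncarriers,
            "control_carriers": t.control_carriers,
            "control_noncarriers": t.control_noncarriers,
            "odds_ratio": self.odds_ratio, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "p_fisher": self.p_fisher,
            "p_adjusted": self.p_adjusted,
        }


def burden_scan(
    cohort: Cohort,
    carrier_cats: Mapping[str, object],
    labels: Optional[Sequence] = None,
    eoad_boundary: float = 65.0,
    bonferroni_family: Optional[int] = None,
    haldane_anscombe: bool = False,
) -> list[BurdenResult]:
    """One BurdenResult per label x stratum (ALL, EOAD, LOAD).

    ``carrier_cats`` maps individual id -> label (Category or subcategory
    string).  The Bonferroni family defaults to the number of tests emitted by
    this scan.
    """
    if labels is None:
        seen = {v for v in carrier_cats.values() if v not in (Category.WT,)}
        labels = sorted(seen, key=str)
    results = []
    for label in labels:
        for stratum in default_strata(eoad_boundary):
            table = build_table(cohort, carrier_cats, label, stratum)
            orr = odds_ratio_wald(table, haldane_anscombe=haldane_anscombe)
            results.append(
                BurdenResult(
                    label=str(label), stratum=stratum.name, table=table,
                    odds_ratio=orr.odds_ratio, ci_low=orr.ci_low,
                    ci_high=orr.ci_high, p_fisher=fisher_p(table),
                )
            )
    adj = bonferroni([r.p_fisher for r in results], bonferroni_family)
    for r, p in zip(results, adj):
        r.p_adjusted = p
    return results


def burden_frame(results: Sequence[BurdenResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


# -- covariate-adjusted models ------------------------------------------


def _design(
    cohort: Cohort, carrier_cats: Mapping[str, object], label
) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    """(y, X, column names, n_dropped) for logistic models; individuals with
    missing APOE or PCs are dropped."""
    rows, y = [], []
    dropped = 0
    for ind in cohort.individuals:
        if ind.apoe_e4_count is None or ind.pcs is None:
            dropped += 1
            continue
        carrier = 1.0 if carrier_cats.get(ind.id) == label else 0.0
        rows.append([1.0, carrier, float(ind.apoe_e4_count), *ind.pcs])
        y.append(1.0 if ind.status == "case" else 0.0)
    names = ["const", "carrier", "apoe_e4"] + [f"pc{k}" for k in range(1, 7)]
    return np.asarray(y), np.asarray(rows), names, dropped


def _fit_logit(y: np.ndarray, X: np.ndarray):
    """Maximum-likelihood logistic fit; Newton with a BFGS fallback for flat
    or near-separated likelihoods.  Returns None when neither converges."""
    import warnings as _warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        _warnings.simplefilter("ignore", RuntimeWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
            if fit.mle_retvals.get("converged", True):
                return fit
        except Exception:
            pass
        try:
            fit = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=500)
            if fit.mle_retvals.get("converged", True):
                return fit
        except Exception:
            pass
    return None


def adjusted_burden(
    cohort: Cohort, carrier_cats: Mapping[str, object], label
) -> dict:
    """Carrier-status log-OR from a logistic model of case status on carrier
    indicator + APOE-e4 allele count + PC1..PC6.

    Returns beta, se, p, odds_ratio, CI, n_used, n_dropped and a
    ``separation`` flag (NA standard error when the likelihood is degenerate).
    """
    y, X, names, dropped = _design(cohort, carrier_cats, label)
    if X.size == 0 or X[:, 1].sum() == 0:
        raise ValueError(f"no carriers of {label} with complete covariates")
    carriers = X[:, 1] == 1
    separation = y[carriers].min() == y[carriers].max() and carriers.sum() > 0
    fit = _fit_logit(y, X)
    if fit is None or separation:
        beta = float(fit.params[1]) if fit is not None else math.inf
        return {
            "beta": beta, "se": None, "p": None, "odds_ratio": None,
            "ci_low": None, "ci_high": None, "separation": True,
            "n_used": int(len(y)), "n_dropped": dropped,
        }
    beta, se = float(fit.params[1]), float(fit.bse[1])
    return {
        "beta": beta, "se": se, "p": float(fit.pvalues[1]),
        "odds_ratio": math.exp(beta),
        "ci_low": math.exp(beta - Z_95 * se),
        "ci_high": math.exp(beta + Z_95 * se),
        "separation": False, "n_used": int(len(y)), "n_dropped": dropped,
    }


def apoe_interaction_lrt(
    cohort: Cohort, carrier_cats: Mapping[str, object], label
) -> dict:
    """LRT of additive (carrier + APOE) vs interaction (carrier x APOE)
    logistic models, PCs as covariates.  chi2 with df = parameter difference."""
    y, X, names, dropped = _design(cohort, carrier_cats, label)
    if X.size == 0 or X[:, 1].sum() == 0:
        raise ValueError(f"no carriers of {label} with complete covariates")
    X_full = np.column_stack([X, X[:, 1] * X[:, 2]])
    fit_add = _fit_logit(y, X)
    fit_full = _fit_logit(y, X_full)
    if fit_add is None or fit_full is None:
        raise RuntimeError("logistic fits did not converge")
    stat = 2.0 * (fit_full.llf - fit_add.llf)
    df = X_full.shape[1] - X.shape[1]
    p = float(stats.chi2.sf(max(stat, 0.0), df))
    return {"lrt_stat": float(stat), "df": df, "p_interaction": p,
            "n_used": int(len(y)), "n_dropped": dropped}
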