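"""Gross attributable fractions (Levin) with Fleiss-style confidence
intervals and the low-AF grouping rule.

The gross attributable fraction of a condition is the fraction of the
overall disability rate that would be avoided were the condition eliminated,

    AF = Pe (RR - 1) / (1 + Pe (RR - 1)),

with Pe the (survey-weighted) prevalence of the condition and RR the crude
relative risk of disability given the condition.  Gross AFs ignore
co-morbidity, so their sum across conditions routinely exceeds 1; they are
used here only descriptively and to decide which low-contribution conditions
(AF <= 15% by default) are merged into a single "other diseases" factor
before the average-attributable-fraction analysis.

Confidence intervals are symmetric on the log(1 - AF) scale with the
delta-method variance under multinomial (cross-sectional) sampling of the
2x2 table,

    Var[ln(1 - AF)] = a/(a+c)^2 + c (1/c - 1/(c+d) - 1/(a+c))^2
                      + d/(c+d)^2 - 1/n,

where a,b count disabled/non-disabled among the exposed and c,d among the
unexposed (verified against a multinomial bootstrap in the test suite).
Under weighting the four cells are rescaled to the Kish effective sample
size before the variance is evaluated, since the count formula presumes
unweighted observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .weighting import kish_effective_n, taylor_mean_variance

OTHER_GROUP_NAME = "other_diseases"
DEFAULT_AF_GROUP_THRESHOLD = 0.15


class AFError(ValueError):
    pass


@dataclass(frozen=True)
class AFResult:
    condition: str
    pe: float
    rr: float
    af: float
    ci_low: float
    ci_high: float
    definition: Optional[str] = None
    age_class: Optional[str] = None


def weighted_prevalence(
    records: pd.DataFrame,
    indicator: str,
    weights: str | pd.Series | np.ndarray,
    strata: Optional[str] = None,
    level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Survey-weighted prevalence sum(w x)/sum(w) with a Taylor-linearized
    normal-approximation CI."""
    x = records[indicator].astype(float).to_numpy()
    w = records[weights].to_numpy() if isinstance(weights, str) else np.asarray(weights, float)
    if (w < 0).any():
        raise AFError("weights must be nonnegative")
    W = w.sum()
    if W == 0:
        raise AFError("total weight is zero")
    p = float((w * x).sum() / W)
    strat = records[strata].to_numpy() if strata is not None else None
    var = taylor_mean_variance(x, w, strat)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return p, (p - half, p + half)


def weighted_2x2(
    records: pd.DataFrame,
    condition: str,
    outcome: str,
    weights: str | pd.Series | np.ndarray,
) -> tuple[float, float, float, float]:
    """Weighted cell totals (a, b, c, d): exposed disabled, exposed not,
    unexposed disabled, unexposed not."""
    e = records[condition].astype(bool).to_numpy()
    y = records[outcome].astype(bool).to_numpy()
    w = records[weights].to_numpy() if isinstance(weights, str) else np.asarray(weights, float)
    a = float(w[e & y].sum())
    b = float(w[e & ~y].sum())
    c = float(w[~e & y].sum())
    d = float(w[~e & ~y].sum())
    return a, b, c, d


def estimate_rr(
    records: pd.DataFrame,
    condition: str,
    outcome: str,
    weights: str | pd.Series | np.ndarray,
    continuity: float = 0.0,
) -> float:
    """Crude weighted risk ratio: weighted disability risk among the exposed
    over the risk among the unexposed.

    The crude (not covariate-adjusted) ratio is what Levin's formula
    presumes; the adjusted analysis is the AAF machinery.
    """
    a, b, c, d = weighted_2x2(records, condition, outcome, weights)
    if a + b == 0 or c + d == 0:
        raise AFError("both exposure groups must have positive weighted size")
    risk_u = (c + continuity) / (c + d + 2 * continuity)
    if risk_u == 0:
        raise AFError(
            "zero weighted risk among the unexposed: RR undefined "
            "(consider the continuity-correction option)"
        )
    risk_e = (a + continuity) / (a + b + 2 * continuity)
    return float(risk_e / risk_u)


def standardized_rr(
    records: pd.DataFrame,
    condition: str,
    outcome: str,
    covariates: Sequence[str],
    weights: str,
) -> float:
    """Covariate-standardized risk ratio by g-computation on a weighted
    logistic fit: weighted mean predicted risk with the condition set to 1
    for everyone over the mean with it set to 0.  Optional alternative to
    the crude RR for Levin's formula."""
    from .aaf import fit_disability_model

    res = fit_disability_model(records, [condition], list(covariates), weights, outcome)
    w = records[weights].to_numpy()
    X = res.model.exog
    names = list(res.model.exog_names)
    params = np.asarray(res.params)
    col = names.index(condition)
    lp = X @ params
    beta = params[col]
    risk0 = float((w * expit(lp - beta * X[:, col])).sum() / w.sum())
    risk1 = float((w * expit(lp + beta * (1.0 - X[:, col]))).sum() / w.sum())
    if risk0 <= 0:
        raise AFError("standardized unexposed risk is zero")
    return risk1 / risk0


def levin_af(pe: float, rr: float) -> float:
    """Levin's attributable fraction Pe(RR-1)/(1+Pe(RR-1))."""
    if not 0 <= pe <= 1:
        raise AFError(f"Pe must lie in [0,1], got {pe}")
    if rr <= 0:
        raise AFError(f"RR must be positive, got {rr}")
    x = pe * (rr - 1.0)
    if 1.0 + x <= 0:
        raise AFError("degenerate Levin denominator")
    return x / (1.0 + x)


def fleiss_ci(
    a: float,
    b: float,
    c: float,
    d: float,
    n_eff: Optional[float] = None,
    level: float = 0.95,
    continuity: float = 0.0,
) -> tuple[float, float]:
    """CI for the attributable fraction from a cross-sectional 2x2 table,
    symmetric on the log(1 - AF) scale.

    Cells may be weighted totals; supply ``n_eff`` (Kish effective n) to
    rescale them to the information actually carried by the weighted sample.
    A zero cell is an error unless a continuity correction is requested.
    """
    cells = np.array([a, b, c, d], dtype=float) + continuity
    if (cells <= 0).any():
        raise AFError(
            "all four cells must be positive for the Fleiss-style CI "
            "(consider continuity=0.5)"
        )
    if n_eff is not None:
        cells = cells * (n_eff / cells.sum())
    a_, b_, c_, d_ = cells
    n = cells.sum()
    # 1 - AF = [c/(c+d)] / [(a+c)/n]
    log_comp = np.log(c_ * n) - np.log(c_ + d_) - np.log(a_ + c_)
    var = (
        a_ / (a_ + c_) ** 2
        + c_ * (1.0 / c_ - 1.0 / (c_ + d_) - 1.0 / (a_ + c_)) ** 2
        + d_ / (c_ + d_) ** 2
        - 1.0 / n
    )
    z = stats.norm.ppf(0.5 + level / 2)
    lo = 1.0 - np.exp(log_comp + z * np.sqrt(var))
    hi = 1.0 - np.exp(log_comp - z * np.sqrt(var))
    return float(lo), float(hi)


def af_from_table(
    records: pd.DataFrame,
    condition: str,
    outcome: str,
    weights: str,
    strata: Optional[str] = None,
    level: float = 0.95,
    definition: Optional[str] = None,
    age_class: Optional[str] = None,
) -> AFResult:
    """Full gross-AF computation for one condition x outcome on weighted
    microdata: weighted prevalence, crude weighted RR, Levin AF, Fleiss CI."""
    pe, _ = weighted_prevalence(records, condition, weights, strata=strata)
    rr = estimate_rr(records, condition, outcome, weights)
    af = levin_af(pe, rr)
    a, b, c, d = weighted_2x2(records, condition, outcome, weights)
    n_eff = kish_effective_n(records[weights])
    lo, hi = fleiss_ci(a, b, c, d, n_eff=n_eff, level=level)
    return AFResult(condition, pe, rr, af, lo, hi, definition, age_class)


def group_low_af(
    af_by_condition: Mapping[str, float] | Sequence[AFResult],
    threshold: float = DEFAULT_AF_GROUP_THRESHOLD,
) -> tuple[list[str], list[str]]:
    """Split conditions into retained factors and the merged "other
    diseases" group (gross AF <= threshold, ties grouped).

    When AF results are available for several age classes, pass the
    *union* of low-AF conditions found across classes (the default pipeline
    behaviour) so one merged list is used everywhere.
    Returns ``(retained, grouped)`` preserving input order.
    """
    if not isinstance(af_by_condition, Mapping):
        af_by_condition = {r.condition: r.af for r in af_by_condition}
    retained = [c for c, v in af_by_condition.items() if v > threshold]
    grouped = [c for c, v in af_by_condition.items() if v <= threshold]
    if not retained:
        raise AFError("all conditions fall at or below the grouping threshold")
    return retained, grouped


def apply_grouping(
    records: pd.DataFrame,
    grouped: Sequence[str],
    other_name: str = OTHER_GROUP_NAME,
) -> pd.DataFrame:
    """Add an ``other_diseases`` indicator = OR over the grouped conditions."""
    out = records.copy()
    if grouped:
        out[other_name] = out[list(grouped)].astype(bool).any(axis=1)
    return out
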