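"""Survey weight chain: design weight x non-response adjustment x calibration.

The final analysis weight per respondent is built in three stages, mirroring
standard complex-survey practice:

1. *design weight* — inverse of the stratum sampling fraction (set by the
   sampling stage, Horvitz-Thompson);
2. *non-response weight* — design weight divided by a response propensity
   fitted by logistic regression on the full selected sample (respondents
   and non-respondents); non-respondents are then dropped;
3. *calibration* — multiplicative raking (iterative proportional fitting)
   so the weighted sample margins match known population margins, here
   typically geographic area x age class x sex.

Variance of weighted means uses Taylor linearization with a with-replacement
approximation within strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

DEFAULT_PROPENSITY_FLOOR = 0.02


class WeightingError(ValueError):
    """Raised on degenerate propensity models or infeasible calibration."""


@dataclass
class CalibrationReport:
    converged: bool
    n_iterations: int
    max_relative_margin_error: float
    margin_errors: dict


def fit_response_propensity(
    sample: pd.DataFrame,
    predictors: Sequence[str],
    response_col: str = "responded",
    floor: float = DEFAULT_PROPENSITY_FLOOR,
) -> pd.Series:
    """Fit a logistic response-propensity model on the full selected sample.

    Categorical (non-numeric) predictors are dummy-coded.  Fitted
    probabilities below ``floor`` are clipped (the number of clips is
    logged) so that non-response weights stay bounded.
    """
    y = sample[response_col].astype(float)
    if y.isna().any():
        raise WeightingError("response indicator contains missing values")
    if len(predictors) == 0:
        p = float(y.mean())
        props = pd.Series(p, index=sample.index)
    else:
        X = pd.get_dummies(sample[list(predictors)], drop_first=True, dtype=float)
        for col in X.columns:
            if X[col].nunique() <= 1:
                raise WeightingError(f"degenerate predictor (constant): {col}")
        X = sm.add_constant(X, has_constant="add")
        if y.nunique() == 1:
            # all respondents (or none): saturated null fit
            props = pd.Series(float(y.iloc[0]), index=sample.index)
        else:
            try:
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            except Exception as exc:  # pragma: no cover - statsmodels detail
                raise WeightingError(f"propensity model failed: {exc}") from exc
            if not np.all(np.isfinite(res.params)):
                bad = X.columns[~np.isfinite(res.params)].tolist()
                raise WeightingError(f"separation in propensity model: {bad}")
            logger.info("response propensity fit: %s", dict(res.params.round(4)))
            props = pd.Series(np.asarray(res.fittedvalues), index=sample.index)
    n_clipped = int((props < floor).sum())
    if n_clipped:
        logger.warning("clipped %d propensities below floor %.3g", n_clipped, floor)
    return props.clip(lower=floor)


def nonresponse_adjust(
    sample: pd.DataFrame,
    propensity: pd.Series,
    design_weight_col: str = "design_weight",
    response_col: str = "responded",
    floor: float = DEFAULT_PROPENSITY_FLOOR,
) -> pd.DataFrame:
    """Inverse-propensity adjust design weights; drop non-respondents.

    Returns the respondent-only analysis table with ``nonresponse_weight``
    = design_weight / propensity and ``response_propensity`` columns.
    """
    p = propensity.clip(lower=floor)
    if (p <= 0).any() or (p > 1).any():
        raise WeightingError("propensities must lie in (0, 1]")
    out = sample.copy()
    out["response_propensity"] = p
    out["nonresponse_weight"] = out[design_weight_col] / p
    out = out.loc[out[response_col].astype(bool)].copy()
    return out


def _margin_totals(weights: np.ndarray, codes: np.ndarray, n_cat: int) -> np.ndarray:
    return np.bincount(codes, weights=weights, minlength=n_cat)


def calibrate(
    weights: pd.Series | np.ndarray,
    records: pd.DataFrame,
    margins: Mapping[str, Mapping[object, float]],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[pd.Series, CalibrationReport]:
    """Rake weights to the given marginal totals (iterative proportional
    fitting).

    Parameters
    ----------
    weights
        Starting weights (typically the non-response-adjusted weights).
    records
        Respondent table carrying the margin variables as columns.
    margins
        ``{variable: {category: target_total}}``.  Categories must cover
        every value present in the sample, and every category with a
        positive target must be present in the sample.
    tol
        Convergence threshold on the maximum relative margin error.

    Returns the calibrated weights and a convergence report.  Raking
    preserves the weighted interaction structure (odds ratios) of the
    starting weights across the margin variables.
    """
    w = np.asarray(weights, dtype=float).copy()
    if (w < 0).any():
        raise WeightingError("weights must be nonnegative")
    index = records.index
    coded: list[tuple[str, np.ndarray, np.ndarray, list]] = []
    for var, cats in margins.items():
        if var not in records.columns:
            raise WeightingError(f"margin variable not in records: {var}")
        cat_list = list(cats.keys())
        targets = np.array([float(cats[c]) for c in cat_list])
        if (targets <= 0).any():
            raise WeightingError(f"margin totals must be positive: {var}")
        codes = pd.Categorical(records[var], categories=cat_list).codes
        if (codes < 0).any():
            extra = sorted(set(records[var][codes < 0]))
            raise WeightingError(f"sample categories missing from margins[{var!r}]: {extra}")
        counts = np.bincount(codes, minlength=len(cat_list))
        empty = [cat_list[i] for i in range(len(cat_list)) if counts[i] == 0]
        if empty:
            raise WeightingError(f"empty sample cell with positive margin: {var}={empty}")
        coded.append((var, codes, targets, cat_list))

    def max_rel_error(wv: np.ndarray) -> tuple[float, dict]:
        errs = {}
        worst = 0.0
        for var, codes, targets, cat_list in coded:
            tot = _margin_totals(wv, codes, len(cat_list))
            rel = np.abs(tot - targets) / targets
            errs[var] = dict(zip(cat_list, rel))
            worst = max(worst, float(rel.max()))
        return worst, errs

    err, errs = max_rel_error(w)
    it = 0
    while err > tol and it < max_iter:
        for var, codes, targets, cat_list in coded:
            tot = _margin_totals(w, codes, len(cat_list))
            if (tot == 0).any():
                zero = [cat_list[i] for i in np.where(tot == 0)[0]]
                raise WeightingError(f"weighted cell collapsed to zero: {var}={zero}")
            w = w * (targets / tot)[codes]
        it += 1
        err, errs = max_rel_error(w)
    report = CalibrationReport(
        converged=err <= tol,
        n_iterations=it,
        max_relative_margin_error=err,
        margin_errors=errs,
    )
    if not report.converged:
        raise WeightingError(
            f"raking did not converge in {max_iter} iterations; "
            f"max relative margin error {err:.3g}"
        )
    return pd.Series(w, index=index, name="calibrated_weight"), report


class RakingCalibrator(BaseEstimator):
    """Sklearn-style wrapper around :func:`calibrate`.

    Parameters follow the estimator convention so the calibrator can sit in
    model-selection tooling; ``fit`` computes the per-record multiplicative
    adjustment, ``transform`` applies it.
    """

    def __init__(self, margins=None, tol: float = 1e-8, max_iter: int = 100):
        self.margins = margins
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, records: pd.DataFrame, weights):
        w, report = calibrate(weights, records, self.margins, self.tol, self.max_iter)
        self.factors_ = w / np.asarray(weights, dtype=float)
        self.report_ = report
        return self

    def transform(self, weights):
        return np.asarray(weights, dtype=float) * np.asarray(self.factors_)

    def fit_transform(self, records, weights):
        return self.fit(records, weights).transform(weights)


def kish_effective_n(weights) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / (w**2).sum())


def taylor_mean_variance(
    y, weights, strata=None
) -> float:
    """Taylor-linearization variance of the weighted mean sum(w y)/sum(w).

    Treats units as sampled with replacement within strata (one-stage
    approximation); with ``strata=None`` the sample is a single stratum.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    W = w.sum()
    if W <= 0:
        raise WeightingError("total weight must be positive")
    mean = (w * y).sum() / W
    z = w * (y - mean) / W
    if strata is None:
        strata = np.zeros(len(y), dtype=int)
    strata = np.asarray(strata)
    var = 0.0
    for s in np.unique(strata):
        zs = z[strata == s]
        n_h = len(zs)
        if n_h > 1:
            var += n_h / (n_h - 1) * ((zs - zs.mean()) ** 2).sum()
    return float(var)


def build_weight_chain(
    sample: pd.DataFrame,
    propensity_predictors: Sequence[str],
    margins: Optional[Mapping[str, Mapping[object, float]]] = None,
    floor: float = DEFAULT_PROPENSITY_FLOOR,
) -> tuple[pd.DataFrame, Optional[CalibrationReport]]:
    """Run the full chain on a sampled table with design weights.

    Returns the respondent-only table with ``nonresponse_weight`` and
    ``calibrated_weight`` columns (the latter equals the former when no
    margins are supplied) plus the raking report.
    """
    props = fit_response_propensity(sample, propensity_predictors, floor=floor)
    resp = nonresponse_adjust(sample, props, floor=floor)
    report = None
    if margins:
        cal, report = calibrate(resp["nonresponse_weight"], resp, margins)
        resp["calibrated_weight"] = cal
    else:
        resp["calibrated_weight"] = resp["nonresponse_weight"]
    return resp, report
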