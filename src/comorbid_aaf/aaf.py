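"""Average attributable fractions (AAF) for co-morbid risk factors.

The gross attributable fraction of a single condition ignores co-morbidity:
summed over conditions it routinely exceeds 100%.  The AAF resolves this by
partitioning the disability burden across a set K of k factors.  Write
AF(S) for the joint attributable fraction of eliminating the subset S of
factors.  The *sequential* AF of factor i after S is AF(S + {i}) - AF(S);
the AAF of factor i is its sequential AF averaged over all k! orders in
which the factors could be eliminated,

    AAF_i = sum over S subset of K\\{i} of
            |S|! (k - |S| - 1)! / k!  *  (AF(S + {i}) - AF(S)),

i.e. the Shapley value of the set function AF.  Consequently the AAFs are
symmetric, a factor with no effect gets AAF 0, and the AAFs sum exactly to
AF(K), the joint fraction attributable to all factors together — so the sum
can never exceed 100% when AF(K) <= 1.

AF(S) itself comes from model-based standardization (g-computation) on one
survey-weighted logistic regression of the binary disability outcome on all
k factor indicators plus adjustment covariates: with fitted probabilities
p_j at the observed data and p_j(S->0) after setting the factors in S to
zero,

    AF(S) = 1 - sum_j w_j p_j(S->0) / sum_j w_j p_j .

Using predicted (not observed) weighted cases in the denominator makes
AF(empty set) = 0 exact under any model misfit, and evaluating every subset
from the same fitted model makes the subset lattice internally consistent,
so the Shapley efficiency identity holds to machine precision.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

EXACT_MODE_CAP = 12
PERMUTATION_ORACLE_CAP = 8
FACTOR_HARD_CAP = 20
SEPARATION_COEF_BOUND = 30.0


class AAFError(ValueError):
    pass


@dataclass
class AAFResult:
    """Per-factor AAFs for one outcome definition x age class."""

    factors: list[str]
    aaf: dict[str, float]
    af_all: float
    sum_of_aafs: float
    weighted_disabled_total: float
    expected_prevented: dict[str, float]
    expected_prevented_rounded: dict[str, float]
    definition: Optional[str] = None
    age_class: Optional[str] = None
    mode: str = "exact"
    n_perms: Optional[int] = None
    seed: Optional[int] = None
    mc_se: Optional[dict[str, float]] = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "factor": self.factors,
                "aaf": [self.aaf[f] for f in self.factors],
                "expected_prevented_raw": [self.expected_prevented[f] for f in self.factors],
                "expected_prevented_rounded": [
                    self.expected_prevented_rounded[f] for f in self.factors
                ],
            }
        )
        df = df.sort_values("aaf", ascending=False, kind="mergesort").reset_index(drop=True)
        df.insert(0, "rank", np.arange(1, len(df) + 1))
        df["definition"] = self.definition
        df["age_class"] = self.age_class
        df["mode"] = self.mode
        return df


def build_design(
    records: pd.DataFrame,
    factors: Sequence[str],
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Design matrix: intercept, 0/1 factor indicators, covariates
    (non-numeric covariates dummy-coded with first level as reference)."""
    X = pd.DataFrame(index=records.index)
    X["const"] = 1.0
    for f in factors:
        col = records[f]
        vals = set(pd.unique(col.astype(int)))
        if not vals <= {0, 1}:
            raise AAFError(f"factor {f!r} is not binary")
        X[f] = col.astype(float)
    for c in covariates:
        col = records[c]
        if pd.api.types.is_bool_dtype(col):
            X[c] = col.astype(float)
        elif pd.api.types.is_numeric_dtype(col):
            X[c] = col.astype(float)
        else:
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
    return X


def fit_disability_model(
    records: pd.DataFrame,
    factor_set: Sequence[str],
    covariates: Sequence[str],
    weights: str | pd.Series | np.ndarray,
    outcome: str = "disabled",
):
    """Survey-weighted maximum-likelihood logistic fit of the outcome on all
    factors plus covariates.  Raises on non-convergence or separation,
    naming the offending terms."""
    y = records[outcome].astype(float)
    if not set(pd.unique(y)) <= {0.0, 1.0}:
        raise AAFError(f"outcome {outcome!r} is not binary")
    w = records[weights] if isinstance(weights, str) else pd.Series(np.asarray(weights, float), index=records.index)
    if (w < 0).any():
        raise AAFError("weights must be nonnegative")
    for f in factor_set:
        if records[f].astype(bool).nunique() < 2:
            raise AAFError(f"factor {f!r} has no variation in the data (separation)")
    X = build_design(records, factor_set, covariates)
    model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
    res = model.fit(maxiter=200)
    if not res.converged:
        raise AAFError("weighted logistic fit did not converge")
    bad = [n for n, v in res.params.items() if not np.isfinite(v) or abs(v) > SEPARATION_COEF_BOUND]
    if bad:
        raise AAFError(f"separation suspected for terms: {bad}")
    logger.info(
        "disability model (%s): deviance=%.2f, coef=%s",
        outcome,
        res.deviance,
        dict(res.params.round(3)),
    )
    return res


class SubsetAFEvaluator:
    """Memoized AF(S) over the subset lattice of a factor set.

    AF values are keyed by bitmask (bit j = factor_set[j]).  Because the
    model is logistic, zeroing the factors in S only subtracts their linear
    contributions, so each subset costs one expit over n records.
    """

    def __init__(
        self,
        model_result,
        records: pd.DataFrame,
        weights,
        factor_set: Sequence[str],
        denominator: str = "predicted",
        outcome: Optional[str] = None,
    ):
        self.factor_set = list(factor_set)
        self.k = len(self.factor_set)
        if self.k < 1:
            raise AAFError("factor set is empty")
        if self.k > FACTOR_HARD_CAP:
            raise AAFError(f"factor set exceeds hard cap of {FACTOR_HARD_CAP}")
        self._w = (
            records[weights].to_numpy()
            if isinstance(weights, str)
            else np.asarray(weights, dtype=float)
        )
        X = model_result.model.exog
        names = list(model_result.model.exog_names)
        params = np.asarray(model_result.params)
        self._lp_obs = X @ params
        # per-factor linear contribution beta_j * x_j
        contrib = np.empty((len(self._lp_obs), self.k))
        for j, f in enumerate(self.factor_set):
            if f not in names:
                raise AAFError(f"factor {f!r} has no coefficient in the model")
            col = names.index(f)
            contrib[:, j] = params[col] * X[:, col]
        self._contrib = contrib
        p_obs = expit(self._lp_obs)
        if denominator == "predicted":
            self._denom = float((self._w * p_obs).sum())
        elif denominator == "observed":
            if outcome is None:
                y = np.asarray(model_result.model.endog, dtype=float)
            else:
                y = records[outcome].astype(float).to_numpy()
            self._denom = float((self._w * y).sum())
        else:
            raise AAFError(f"unknown denominator mode: {denominator!r}")
        if self._denom <= 0:
            raise AAFError("no (predicted) disabled cases: AF undefined")
        self._cache: dict[int, float] = {0: 0.0 if denominator == "predicted" else
                                         1.0 - float((self._w * p_obs).sum()) / self._denom}
        self.n_evaluations = 0

    def af_mask(self, mask: int) -> float:
        """AF(S) for the subset encoded by ``mask``."""
        if mask in self._cache:
            return self._cache[mask]
        sel = [j for j in range(self.k) if mask >> j & 1]
        lp = self._lp_obs - self._contrib[:, sel].sum(axis=1)
        af = 1.0 - float((self._w * expit(lp)).sum()) / self._denom
        self._cache[mask] = af
        self.n_evaluations += 1
        return af

    def af(self, subset: Sequence[str]) -> float:
        """AF(S) for a subset given by factor names."""
        mask = 0
        for f in subset:
            try:
                mask |= 1 << self.factor_set.index(f)
            except ValueError:
                raise AAFError(f"{f!r} is not in the factor set") from None
        return self.af_mask(mask)


def af_of_subset(
    model_result,
    records: pd.DataFrame,
    weights,
    subset: Sequence[str],
    factor_set: Sequence[str],
    denominator: str = "predicted",
) -> float:
    """One-off AF(S) by g-computation (see :class:`SubsetAFEvaluator`)."""
    ev = SubsetAFEvaluator(model_result, records, weights, factor_set, denominator)
    return ev.af(subset)


def aaf_exact(af_evaluator: Callable[[int], float], k: int) -> np.ndarray:
    """Exact Shapley-weighted AAFs from a bitmask AF evaluator.

    The evaluator is called at most 2^k times (memoize it for lattices that
    are expensive to evaluate).
    """
    if k < 1:
        raise AAFError("k must be >= 1")
    if k > EXACT_MODE_CAP:
        raise AAFError(
            f"k={k} exceeds the exact-mode cap ({EXACT_MODE_CAP}); use aaf_montecarlo"
        )
    # Shapley weight depends only on |S|
    wgt = [1.0 / (k * math.comb(k - 1, s)) for s in range(k)]
    aaf = np.zeros(k)
    full = 1 << k
    af_vals = np.empty(full)
    for mask in range(full):
        af_vals[mask] = af_evaluator(mask)
    for i in range(k):
        bit = 1 << i
        rest = [m for m in range(full) if not m & bit]
        for m in rest:
            s = bin(m).count("1")
            aaf[i] += wgt[s] * (af_vals[m | bit] - af_vals[m])
    return aaf


def aaf_permutation_oracle(af_evaluator: Callable[[int], float], k: int) -> np.ndarray:
    """Brute-force AAF: average sequential AF increments over all k!
    elimination orders.  Exponential cost; the independent check for
    :func:`aaf_exact`."""
    if k > PERMUTATION_ORACLE_CAP:
        raise AAFError(f"k={k} exceeds the permutation-oracle cap ({PERMUTATION_ORACLE_CAP})")
    totals = np.zeros(k)
    n_perm = 0
    for perm in itertools.permutations(range(k)):
        mask = 0
        prev = af_evaluator(0)
        for i in perm:
            mask |= 1 << i
            cur = af_evaluator(mask)
            totals[i] += cur - prev
            prev = cur
        n_perm += 1
    return totals / n_perm


def aaf_montecarlo(
    af_evaluator: Callable[[int], float],
    k: int,
    n_perms: int,
    seed: Optional[int] = None,
    without_replacement: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte Carlo AAF over sampled elimination orders.

    Returns ``(aaf, mc_standard_error)`` per factor.  With
    ``without_replacement=True`` and ``n_perms >= k!`` all distinct
    permutations are enumerated once (result then equals the exact AAF).
    """
    if n_perms < 100:
        raise AAFError("n_perms must be >= 100")
    rng = np.random.default_rng(seed)
    if without_replacement and n_perms >= math.factorial(k):
        perms = list(itertools.permutations(range(k)))
    else:
        perms = [rng.permutation(k) for _ in range(n_perms)]
    sums = np.zeros(k)
    sq_sums = np.zeros(k)
    for perm in perms:
        mask = 0
        prev = af_evaluator(0)
        for i in perm:
            mask |= 1 << int(i)
            cur = af_evaluator(mask)
            inc = cur - prev
            sums[int(i)] += inc
            sq_sums[int(i)] += inc * inc
            prev = cur
    m = len(perms)
    mean = sums / m
    var = np.maximum(sq_sums / m - mean**2, 0.0)
    se = np.sqrt(var / m)
    return mean, se


def expected_prevented(
    aaf: float, weighted_disabled_total: float, round_to: int = 10_000
) -> tuple[float, float]:
    """Expected number of disabled people prevented by eliminating the
    factor: AAF x weighted disabled count, raw and rounded (default to the
    nearest 10,000, the precision used when quoting such counts)."""
    if weighted_disabled_total < 0:
        raise AAFError("weighted disabled total must be nonnegative")
    raw = aaf * weighted_disabled_total
    rounded = round(raw / round_to) * round_to if round_to else raw
    return float(raw), float(rounded)


class AverageAttributableFraction(BaseEstimator):
    """Survey-weighted, covariate-adjusted average attributable fractions.

    Fits one weighted logistic regression of a binary outcome on all factor
    indicators plus adjustment covariates, then decomposes the joint
    attributable fraction across factors by exact Shapley enumeration
    (``mode="exact"``, k <= 12) or Monte Carlo over elimination orders
    (``mode="montecarlo"``).

    Parameters
    ----------
    factors : list of str
        Binary exposure columns (the condition groups after low-AF merging).
    covariates : list of str
        Adjustment columns; non-numeric ones are dummy-coded.
    mode : {"exact", "montecarlo", "permutation"}
    n_perms : int
        Permutations sampled in Monte Carlo mode.
    seed : int or None
        Seed for Monte Carlo mode.
    denominator : {"predicted", "observed"}
        Weighted-case denominator of AF(S); "predicted" makes AF(empty)=0
        exact.

    Attributes
    ----------
    model_result_ : statsmodels GLMResults of the weighted logistic fit.
    aaf_ : pd.Series, AAF per factor.
    af_all_ : float, joint AF of eliminating every factor.
    sum_aaf_ : float, sum of the per-factor AAFs (= ``af_all_`` in exact mode).
    mc_se_ : pd.Series or None, Monte Carlo standard errors.
    """

    def __init__(
        self,
        factors: Optional[Sequence[str]] = None,
        covariates: Sequence[str] = (),
        mode: str = "exact",
        n_perms: int = 5000,
        seed: Optional[int] = None,
        denominator: str = "predicted",
    ):
        self.factors = factors
        self.covariates = covariates
        self.mode = mode
        self.n_perms = n_perms
        self.seed = seed
        self.denominator = denominator

    def fit(self, X: pd.DataFrame, y, sample_weight=None):
        if self.factors is None:
            raise AAFError("factors must be specified")
        factors = list(self.factors)
        k = len(factors)
        data = X.copy()
        data["__outcome__"] = np.asarray(y)
        if sample_weight is None:
            sample_weight = np.ones(len(data))
        self.model_result_ = fit_disability_model(
            data, factors, list(self.covariates), sample_weight, outcome="__outcome__"
        )
        ev = SubsetAFEvaluator(
            self.model_result_, data, sample_weight, factors, denominator=self.denominator
        )
        self.evaluator_ = ev
        self.mc_se_ = None
        if self.mode == "exact":
            vals = aaf_exact(ev.af_mask, k)
        elif self.mode == "permutation":
            vals = aaf_permutation_oracle(ev.af_mask, k)
        elif self.mode == "montecarlo":
            vals, se = aaf_montecarlo(ev.af_mask, k, self.n_perms, self.seed)
            self.mc_se_ = pd.Series(se, index=factors)
        else:
            raise AAFError(f"unknown mode: {self.mode!r}")
        self.n_factors_ = k
        self.aaf_ = pd.Series(vals, index=factors, name="aaf")
        self.af_all_ = float(ev.af_mask((1 << k) - 1))
        self.sum_aaf_ = float(vals.sum())
        return self

    def af_of_subset(self, subset: Sequence[str]) -> float:
        return self.evaluator_.af(subset)


def aaf_analysis(
    records: pd.DataFrame,
    outcome: str,
    factors: Sequence[str],
    covariates: Sequence[str],
    weights: str,
    mode: str = "exact",
    n_perms: int = 5000,
    seed: Optional[int] = None,
    definition: Optional[str] = None,
    age_class: Optional[str] = None,
    round_to: int = 10_000,
) -> AAFResult:
    """End-to-end AAF table for one outcome on weighted microdata,
    including expected prevented-case counts (AAF x weighted number of
    disabled respondents)."""
    est = AverageAttributableFraction(
        factors=list(factors), covariates=list(covariates), mode=mode,
        n_perms=n_perms, seed=seed,
    ).fit(records, records[outcome], sample_weight=records[weights].to_numpy())
    n_disabled = float(
        (records[weights].to_numpy() * records[outcome].astype(float).to_numpy()).sum()
    )
    prevented_raw, prevented_rounded = {}, {}
    for f in factors:
        raw, rnd = expected_prevented(float(est.aaf_[f]), n_disabled, round_to)
        prevented_raw[f] = raw
        prevented_rounded[f] = rnd
    return AAFResult(
        factors=list(factors),
        aaf={f: float(est.aaf_[f]) for f in factors},
        af_all=est.af_all_,
        sum_of_aafs=est.sum_aaf_,
        weighted_disabled_total=n_disabled,
        expected_prevented=prevented_raw,
        expected_prevented_rounded=prevented_rounded,
        definition=definition,
        age_class=age_class,
        mode=mode,
        n_perms=n_perms if mode == "montecarlo" else None,
        seed=seed if mode == "montecarlo" else None,
        mc_se=dict(est.mc_se_) if est.mc_se_ is not None else None,
    )
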