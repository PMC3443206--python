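"""Synthetic household-survey generator with known ground truth.

Emulates the statistical structure of a national two-stage disability
survey: a household population with correlated chronic-condition indicators
(co-morbidity via a single shared Gaussian latent frailty), a known logistic
disability-generating model for three outcomes (self-reported disability,
any-ADL-restriction disability, severe disability), six ADL items consistent
with those outcomes, stratification by presumed disability severity (4
levels) crossed with geographic areas, unequal stratum sampling fractions
(severe strata oversampled), and covariate-dependent non-response.

Because the generating model is known, true attributable fractions of every
condition subset — and hence true average attributable fractions — are
available from :func:`true_aaf_oracle` for parameter-recovery studies.

Default parameters emulate the conditions of a large European household
survey: 12 condition groups with adult prevalences between 2% and 65%,
overall outcome prevalences of roughly 12% (self-reported), 4% (ADL
restriction) and 1.4% (severe), and a marginal response rate calibrated to
76.6%.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .aaf import EXACT_MODE_CAP, aaf_exact
from .outcomes import ADL_ITEMS, CONDITION_GROUPS

logger = logging.getLogger(__name__)

AGE_CLASSES = ("18-40", "40-65", ">65")

# numeric covariate features entering every logistic model
COVARIATE_FEATURES = (
    "age_c",
    "sex_male",
    "living_alone",
    "married",
    "edu_mid",
    "edu_high",
    "res_urban_small",
    "res_urban_large",
)


class SpecError(ValueError):
    """Raised when a PopulationSpec violates its invariants."""


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal covariate distributions of the adult household population."""

    age_beta: tuple[float, float] = (1.9, 3.1)  # mean age ~ 48 years
    age_range: tuple[float, float] = (18.0, 98.0)
    p_male: float = 0.48
    marital_levels: tuple[str, ...] = ("single", "married", "widowed_divorced")
    marital_probs: tuple[float, ...] = (0.30, 0.55, 0.15)
    education_levels: tuple[str, ...] = ("primary", "secondary", "tertiary")
    education_probs: tuple[float, ...] = (0.35, 0.40, 0.25)
    residence_levels: tuple[str, ...] = ("rural", "urban_lt200k", "urban_ge200k")
    residence_probs: tuple[float, ...] = (0.25, 0.35, 0.40)
    living_alone_intercept: float = -1.6  # logistic on age
    living_alone_age_slope: float = 0.25  # per decade of age


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic model: intercept + condition log-odds + covariate log-odds."""

    intercept: float
    condition_log_odds: Mapping[str, float]
    covariate_log_odds: Mapping[str, float]

    def linear_predictor(
        self, conditions: pd.DataFrame, features: pd.DataFrame
    ) -> np.ndarray:
        lp = np.full(len(conditions), self.intercept, dtype=float)
        for c, beta in self.condition_log_odds.items():
            lp += beta * conditions[c].to_numpy(dtype=float)
        for f, gamma in self.covariate_log_odds.items():
            lp += gamma * features[f].to_numpy(dtype=float)
        return lp


@dataclass(frozen=True)
class DesignSpec:
    """4 presumed-severity levels x geographic areas, Bernoulli or
    fixed-size sampling within stratum."""

    n_areas: int = 11
    severity_fractions: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.08, 2: 0.25, 3: 0.50, 4: 0.90}
    )
    area_multipliers: Optional[Mapping[int, float]] = None  # default uniform
    mode: str = "bernoulli"  # or "fixed"


@dataclass(frozen=True)
class NonresponseModel:
    """Logistic response-propensity model on covariates and presumed
    severity.  If ``target_rate`` is set, the intercept is solved on the
    sample so the mean propensity matches it."""

    coefficients: Mapping[str, float] = field(
        default_factory=lambda: {
            "age_c": -0.05,
            "sex_male": -0.15,
            "living_alone": -0.10,
            "presumed_severity": -0.15,
        }
    )
    intercept: float = 1.2
    target_rate: Optional[float] = 0.766


def _default_prevalences() -> dict[str, float]:
    # overall adult-population prevalences typical of the 12 groups
    return {
        "cancer": 0.019,
        "cardiovascular": 0.212,
        "dermatological": 0.062,
        "digestive": 0.046,
        "endocrine": 0.188,
        "musculoskeletal": 0.287,
        "neurological": 0.101,
        "psychiatric": 0.063,
        "respiratory": 0.115,
        "sensorial": 0.654,
        "sequelae_of_injury": 0.035,
        "urological": 0.048,
    }


def _default_disability_model() -> dict[str, OutcomeModel]:
    cond_dis = {
        "cancer": 0.40,
        "cardiovascular": 0.70,
        "dermatological": 0.10,
        "digestive": 0.30,
        "endocrine": 0.50,
        "musculoskeletal": 0.90,
        "neurological": 1.30,
        "psychiatric": 0.90,
        "respiratory": 0.25,
        "sensorial": 0.20,
        "sequelae_of_injury": 0.60,
        "urological": 0.90,
    }
    cov_dis = {
        "age_c": 0.55,
        "sex_male": -0.10,
        "living_alone": 0.20,
        "married": -0.10,
        "edu_mid": -0.20,
        "edu_high": -0.40,
        "res_urban_small": 0.05,
        "res_urban_large": 0.05,
    }
    cond_sr = {
        "cancer": 0.45,
        "cardiovascular": 0.55,
        "dermatological": 0.15,
        "digestive": 0.35,
        "endocrine": 0.50,
        "musculoskeletal": 1.00,
        "neurological": 0.80,
        "psychiatric": 1.00,
        "respiratory": 0.35,
        "sensorial": 0.55,
        "sequelae_of_injury": 0.70,
        "urological": 0.55,
    }
    cov_sr = {
        "age_c": 0.25,
        "sex_male": -0.05,
        "living_alone": 0.15,
        "married": -0.10,
        "edu_mid": -0.15,
        "edu_high": -0.30,
        "res_urban_small": 0.0,
        "res_urban_large": 0.0,
    }
    return {
        "disabled": OutcomeModel(-4.9, cond_dis, cov_dis),
        # same slopes, lower intercept: severe nests inside disabled
        "severe": OutcomeModel(-6.1, cond_dis, cov_dis),
        "self_reported": OutcomeModel(-3.1, cond_sr, cov_sr),
    }


@dataclass(frozen=True)
class PopulationSpec:
    """Generative parameters of the synthetic population and survey design."""

    population_size: int = 120_000
    condition_names: tuple[str, ...] = CONDITION_GROUPS
    marginal_prevalences: Mapping[str, float] = field(default_factory=_default_prevalences)
    comorbidity_loading: Mapping[str, float] = field(
        default_factory=lambda: {c: (0.4 if c == "sensorial" else 0.6) for c in CONDITION_GROUPS}
    )
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    disability_model: Mapping[str, OutcomeModel] = field(
        default_factory=_default_disability_model
    )
    adl_noise_sd: float = 0.8
    design: DesignSpec = field(default_factory=DesignSpec)
    nonresponse_model: NonresponseModel = field(default_factory=NonresponseModel)
    inclusive_40: bool = False  # age-class boundary convention
    seed: int = 0

    def validate(self) -> None:
        if self.population_size <= 0:
            raise SpecError("population_size must be positive")
        if len(set(self.condition_names)) != len(self.condition_names):
            raise SpecError("condition_names must be unique")
        for c in self.condition_names:
            p = self.marginal_prevalences.get(c)
            if p is None or not 0 <= p < 1:
                raise SpecError(f"marginal_prevalences[{c!r}] must lie in [0,1)")
            if c not in self.comorbidity_loading:
                raise SpecError(f"comorbidity_loading missing condition {c!r}")
        for name, model in self.disability_model.items():
            for c in self.condition_names:
                if c not in model.condition_log_odds:
                    raise SpecError(f"disability_model[{name!r}] missing condition {c!r}")
        for lvl in (1, 2, 3, 4):
            f = self.design.severity_fractions.get(lvl)
            if f is None or not 0 < f <= 1:
                raise SpecError(f"design.severity_fractions[{lvl}] must lie in (0,1]")
        if self.design.n_areas < 1:
            raise SpecError("design.n_areas must be >= 1")


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Deterministic per-stage child generator from the master seed."""
    ss = np.random.SeedSequence([int(seed), int(stage)])
    logger.debug("stage %d child seed entropy: %s", stage, ss.entropy)
    return np.random.default_rng(ss)


def age_class_of(age: np.ndarray, inclusive_40: bool = False) -> np.ndarray:
    """Age classes 18-40 / 40-65 / >65 (half-open [18,40), [40,65), [65,inf)
    by default; ``inclusive_40`` moves exact age 40 into the young class)."""
    age = np.asarray(age, dtype=float)
    young = age < 40 if not inclusive_40 else age <= 40
    old = age >= 65
    out = np.where(young, AGE_CLASSES[0], np.where(old, AGE_CLASSES[2], AGE_CLASSES[1]))
    return out


def covariate_features(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric feature encoding shared by the generator, the oracle, and
    the analysis defaults."""
    feats = pd.DataFrame(index=df.index)
    feats["age_c"] = (df["age"].to_numpy(dtype=float) - 48.0) / 10.0
    feats["sex_male"] = (df["sex"] == "male").astype(float)
    feats["living_alone"] = df["living_alone"].astype(float)
    feats["married"] = (df["marital_status"] == "married").astype(float)
    feats["edu_mid"] = (df["education_level"] == "secondary").astype(float)
    feats["edu_high"] = (df["education_level"] == "tertiary").astype(float)
    feats["res_urban_small"] = (df["residence"] == "urban_lt200k").astype(float)
    feats["res_urban_large"] = (df["residence"] == "urban_ge200k").astype(float)
    return feats


def _draw_conditions(
    spec: PopulationSpec, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Correlated binary conditions via a shared Gaussian latent frailty:
    u_j = loading_j * z + e_j with z, e_j standard normal, condition_j =
    u_j above the threshold matching its marginal prevalence.  Pairwise
    tetrachoric correlation is increasing in the product of loadings."""
    z = rng.standard_normal(n)
    out = {}
    for c in spec.condition_names:
        p = spec.marginal_prevalences[c]
        lam = spec.comorbidity_loading[c]
        if p == 0:
            out[c] = np.zeros(n, dtype=bool)
            continue
        u = lam * z + rng.standard_normal(n)
        thresh = norm.isf(p) * math.sqrt(1.0 + lam**2)
        out[c] = u > thresh
    return pd.DataFrame(out)


def _draw_adl_items(
    severity: np.ndarray,
    disabled: np.ndarray,
    severe: np.ndarray,
    rng: np.random.Generator,
    noise_sd: float,
) -> np.ndarray:
    """Six ADL item scores in {0..4} consistent with the generated outcome
    flags: all zero unless disabled; at least one item >= 1 if disabled;
    at least one item == 4 iff severe."""
    n = len(disabled)
    items = np.zeros((n, len(ADL_ITEMS)), dtype=int)
    idx = np.where(disabled)[0]
    if len(idx) == 0:
        return items
    s = severity[idx]
    lat = s[:, None] + rng.normal(0.0, noise_sd, size=(len(idx), len(ADL_ITEMS)))
    # thresholds on the latent severity scale -> scores 0..3
    scores = np.digitize(lat, bins=[0.0, 1.0, 2.0])  # 0..3
    # enforce at least one restriction for every disabled person
    none_restricted = scores.max(axis=1) == 0
    if none_restricted.any():
        worst = lat[none_restricted].argmax(axis=1)
        scores[np.where(none_restricted)[0], worst] = 1
    # severe: worst item becomes 4 (inability to do it alone)
    sev_rows = np.where(severe[idx])[0]
    if len(sev_rows):
        worst = lat[sev_rows].argmax(axis=1)
        scores[sev_rows, worst] = 4
    items[idx] = scores
    return items


def generate_population(spec: PopulationSpec) -> pd.DataFrame:
    """Generate the full (pre-sampling) household population table.

    One row per person: covariates, condition indicators, ADL items, the
    three outcome flags, presumed severity and area/stratum assignment.
    Byte-identical for a fixed ``spec.seed``.
    """
    spec.validate()
    n = spec.population_size
    cov = spec.covariate_spec

    rng_cov = _stage_rng(spec.seed, 0)
    rng_cond = _stage_rng(spec.seed, 1)
    rng_out = _stage_rng(spec.seed, 2)
    rng_adl = _stage_rng(spec.seed, 3)

    a, b = cov.age_beta
    lo, hi = cov.age_range
    age = lo + (hi - lo) * rng_cov.beta(a, b, size=n)
    df = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "age": age,
            "sex": np.where(rng_cov.random(n) < cov.p_male, "male", "female"),
            "marital_status": rng_cov.choice(cov.marital_levels, size=n, p=cov.marital_probs),
            "education_level": rng_cov.choice(
                cov.education_levels, size=n, p=cov.education_probs
            ),
            "residence": rng_cov.choice(cov.residence_levels, size=n, p=cov.residence_probs),
            "area_id": rng_cov.integers(0, spec.design.n_areas, size=n),
        }
    )
    p_alone = expit(
        cov.living_alone_intercept + cov.living_alone_age_slope * (age - 48.0) / 10.0
    )
    df["living_alone"] = rng_cov.random(n) < p_alone
    df["age_class"] = age_class_of(age, spec.inclusive_40)

    conds = _draw_conditions(spec, n, rng_cond)
    df = pd.concat([df, conds.set_index(df.index)], axis=1)

    feats = covariate_features(df)
    lp_dis = spec.disability_model["disabled"].linear_predictor(conds, feats)
    lp_sev = spec.disability_model["severe"].linear_predictor(conds, feats)
    lp_sr = spec.disability_model["self_reported"].linear_predictor(conds, feats)

    # comonotone coupling: one shared uniform drives both ADL outcomes, so
    # severe => disabled whenever p_severe <= p_disabled, and is enforced
    # by OR-ing regardless
    u = rng_out.random(n)
    disabled = u < expit(lp_dis)
    severe = u < expit(lp_sev)
    disabled = disabled | severe
    self_rep = rng_out.random(n) < expit(lp_sr)

    # latent severity: positive iff disabled under the shared uniform
    with np.errstate(divide="ignore"):
        sev_latent = lp_dis - logit(u)
    items = _draw_adl_items(sev_latent, disabled, severe, rng_adl, spec.adl_noise_sd)
    for j, name in enumerate(ADL_ITEMS):
        df[name] = items[:, j]

    df["self_reported_disabled"] = self_rep
    df["disabled"] = disabled
    df["severely_disabled"] = severe

    any_four = items.max(axis=1) == 4
    any_restriction = items.max(axis=1) >= 1
    df["presumed_severity"] = np.select(
        [any_four, any_restriction, self_rep], [4, 3, 2], default=1
    )
    df["stratum_id"] = (
        "S" + df["presumed_severity"].astype(str) + "-A" + df["area_id"].astype(str)
    )
    return df


def draw_sample(population: pd.DataFrame, spec: PopulationSpec) -> pd.DataFrame:
    """Stratified unequal-probability sample with Horvitz-Thompson design
    weights (1 / stratum sampling fraction).

    Bernoulli sampling within stratum by default; ``spec.design.mode ==
    "fixed"`` draws round(f * N_h) without replacement instead.
    """
    spec.validate()
    rng = _stage_rng(spec.seed, 10)
    design = spec.design
    mult = design.area_multipliers or {}
    frac = np.array(
        [
            min(
                1.0,
                design.severity_fractions[s] * mult.get(int(a), 1.0),
            )
            for s, a in zip(population["presumed_severity"], population["area_id"])
        ]
    )
    if (frac <= 0).any():
        raise SpecError("sampling fraction 0 for a nonempty stratum")
    if design.mode == "bernoulli":
        keep = rng.random(len(population)) < frac
        sample = population.loc[keep].copy()
        sample["sampling_fraction"] = frac[keep]
    elif design.mode == "fixed":
        parts = []
        for (strat, f), grp in population.groupby(
            [population["stratum_id"], pd.Series(frac, index=population.index)], sort=True
        ):
            n_h = int(round(f * len(grp)))
            n_h = max(min(n_h, len(grp)), 1)
            take = rng.choice(grp.index.to_numpy(), size=n_h, replace=False)
            part = grp.loc[np.sort(take)].copy()
            part["sampling_fraction"] = n_h / len(grp)
            parts.append(part)
        sample = pd.concat(parts).sort_index()
    else:
        raise SpecError(f"unknown sampling mode: {design.mode!r}")
    sample["design_weight"] = 1.0 / sample["sampling_fraction"]
    return sample


def apply_nonresponse(sample: pd.DataFrame, spec: PopulationSpec) -> pd.DataFrame:
    """Draw per-record response flags from the logistic non-response model.

    If the model declares a ``target_rate`` the intercept is solved so the
    mean response propensity over this sample equals it.  The realised rate
    is logged.
    """
    spec.validate()
    rng = _stage_rng(spec.seed, 20)
    model = spec.nonresponse_model
    feats = covariate_features(sample)
    feats["presumed_severity"] = sample["presumed_severity"].astype(float)
    lp = np.zeros(len(sample))
    for name, coef in model.coefficients.items():
        lp += coef * feats[name].to_numpy(dtype=float)
    if model.target_rate is not None:
        target = model.target_rate
        c = brentq(lambda c0: expit(c0 + lp).mean() - target, -20.0, 20.0)
    else:
        c = model.intercept
    prop = expit(c + lp)
    out = sample.copy()
    out["responded"] = rng.random(len(sample)) < prop
    logger.info(
        "non-response stage: intercept %.3f, realised response rate %.4f",
        c,
        out["responded"].mean(),
    )
    return out


def simulate_survey(spec: PopulationSpec) -> pd.DataFrame:
    """Population -> stratified sample -> non-response, in one call."""
    pop = generate_population(spec)
    return apply_nonresponse(draw_sample(pop, spec), spec)


def _true_probability(
    spec: PopulationSpec,
    definition: str,
    conds: pd.DataFrame,
    feats: pd.DataFrame,
    zero_mask: int = 0,
) -> np.ndarray:
    """True outcome probability per person under the generating model, with
    the conditions flagged in ``zero_mask`` counterfactually set to 0."""
    conds = conds.copy()
    for j, c in enumerate(spec.condition_names):
        if zero_mask >> j & 1:
            conds[c] = False
    if definition == "disabled":
        # disabled = (u < p_dis) or (u < p_sev) under one shared uniform
        p1 = expit(spec.disability_model["disabled"].linear_predictor(conds, feats))
        p2 = expit(spec.disability_model["severe"].linear_predictor(conds, feats))
        return np.maximum(p1, p2)
    if definition in ("severe", "self_reported"):
        return expit(spec.disability_model[definition].linear_predictor(conds, feats))
    raise SpecError(f"unknown disability definition: {definition!r}")


def true_aaf_oracle(
    spec: PopulationSpec,
    disability_definition: str = "disabled",
    age_class_filter: Optional[str] = None,
    population: Optional[pd.DataFrame] = None,
) -> pd.Series:
    """Ground-truth AAF per condition under the known generating model.

    AF(S) is computed by g-computation with the *true* outcome
    probabilities on the generated population (set the conditions in S to
    zero, recompute probabilities, AF(S) = 1 - E[p(S->0)] / E[p]); the
    subset lattice is then combined with exact Shapley weights.  These are
    the estimands the survey analysis tries to recover.
    """
    spec.validate()
    k = len(spec.condition_names)
    if k > EXACT_MODE_CAP:
        raise SpecError(
            f"oracle supports at most {EXACT_MODE_CAP} conditions; "
            "use the Monte Carlo AAF mode instead"
        )
    if population is None:
        population = generate_population(spec)
    if age_class_filter is not None:
        population = population.loc[population["age_class"] == age_class_filter]
    conds = population[list(spec.condition_names)]
    feats = covariate_features(population)
    denom = _true_probability(spec, disability_definition, conds, feats, 0).sum()
    if denom <= 0:
        raise SpecError("generating model produces no expected cases")

    cache: dict[int, float] = {}

    def af_mask(mask: int) -> float:
        if mask not in cache:
            num = _true_probability(spec, disability_definition, conds, feats, mask).sum()
            cache[mask] = 1.0 - num / denom
        return cache[mask]

    vals = aaf_exact(af_mask, k)
    return pd.Series(vals, index=list(spec.condition_names), name="true_aaf")


def recovery_spec(seed: int = 0, population_size: int = 120_000) -> PopulationSpec:
    """The documented parameter-recovery scenario: five conditions with
    well-separated effects (log-odds 2.0 / 1.5 / 1.0 / 0.6 / 0.3) and
    moderate co-morbidity, so the true AAF ranking is unambiguous."""
    names = ("cond_a", "cond_b", "cond_c", "cond_d", "cond_e")
    prev = {"cond_a": 0.25, "cond_b": 0.20, "cond_c": 0.15, "cond_d": 0.10, "cond_e": 0.10}
    load = {c: 0.5 for c in names}
    betas = {"cond_a": 2.0, "cond_b": 1.5, "cond_c": 1.0, "cond_d": 0.6, "cond_e": 0.3}
    cov = {
        "age_c": 0.5,
        "sex_male": -0.1,
        "living_alone": 0.2,
        "married": -0.1,
        "edu_mid": -0.2,
        "edu_high": -0.4,
        "res_urban_small": 0.0,
        "res_urban_large": 0.0,
    }
    models = {
        "disabled": OutcomeModel(-3.6, betas, cov),
        "severe": OutcomeModel(-4.8, betas, cov),
        "self_reported": OutcomeModel(-2.6, betas, cov),
    }
    return PopulationSpec(
        population_size=population_size,
        condition_names=names,
        marginal_prevalences=prev,
        comorbidity_loading=load,
        disability_model=models,
        seed=seed,
    )
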