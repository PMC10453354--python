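import numpy as np
import pandas as pd
import pytest

from pscikit.associate import (
    add_strata,
    age_adjusted_difference,
    fit_logistic_cohort_adjusted,
    interaction_test,
    odds_ratio_ci,
    stratified_or,
)
from pscikit.errors import SeparationError


def _two_by_two(w_imp, w_tot, m_imp, m_tot):
    outcome = [1] * w_imp + [0] * (w_tot - w_imp) + [1] * m_imp + [0] * (m_tot - m_imp)
    sex = ["woman"] * w_tot + ["man"] * m_tot
    return np.array(outcome), np.array(sex)


class TestLogisticFit:
    def test_mle_equals_crossproduct_or_on_2x2(self):
        # women 10/40 impaired, men 20/40: OR = (20/20)/(10/30) = 3
        outcome, sex = _two_by_two(10, 40, 20, 40)
        fit = fit_logistic_cohort_adjusted(outcome, sex)
        assert np.exp(fit.params["sex_man"]) == pytest.approx(3.0, rel=1e-6)

    def test_wald_interval_closed_form(self):
        outcome, sex = _two_by_two(10, 40, 20, 40)
        fit = fit_logistic_cohort_adjusted(outcome, sex)
        res = odds_ratio_ci(fit)
        se = np.sqrt(1 / 10 + 1 / 30 + 1 / 20 + 1 / 20)
        assert fit.bse["sex_man"] == pytest.approx(se, rel=1e-5)
        assert res.ci_low == pytest.approx(np.exp(np.log(3) - 1.95996 * se), rel=1e-4)
        assert res.ci_high == pytest.approx(np.exp(np.log(3) + 1.95996 * se), rel=1e-4)
        assert res.ci_low == pytest.approx(1.164, abs=2e-3)
        assert res.ci_high == pytest.approx(7.731, abs=2e-2)

    def test_null_effect_large_n(self):
        rng = np.random.default_rng(0)
        n = 20_000
        sex = np.where(rng.random(n) < 0.4, "woman", "man")
        outcome = (rng.random(n) < 0.3).astype(int)
        fit = fit_logistic_cohort_adjusted(outcome, sex)
        assert np.exp(fit.params["sex_man"]) == pytest.approx(1.0, abs=0.1)

    def test_cohort_independent_of_outcome_is_collapsible(self):
        rng = np.random.default_rng(1)
        n = 30_000
        sex = np.where(rng.random(n) < 0.5, "woman", "man")
        cohort = rng.choice(["a", "b", "c"], n)
        p = np.where(sex == "man", 0.35, 0.25)
        outcome = (rng.random(n) < p).astype(int)
        adj = fit_logistic_cohort_adjusted(outcome, sex, cohort)
        crude = fit_logistic_cohort_adjusted(outcome, sex)
        for c in ("b", "c"):
            assert abs(adj.params[f"cohort_{c}"]) < 0.1
        assert adj.params["sex_man"] == pytest.approx(
            crude.params["sex_man"], abs=1e-3)

    def test_reference_group_symmetry(self):
        outcome, sex = _two_by_two(10, 40, 20, 40)
        fit_mw = fit_logistic_cohort_adjusted(outcome, sex)
        flipped = np.where(sex == "man", "woman", "man")
        fit_wm = fit_logistic_cohort_adjusted(outcome, flipped)
        prod = np.exp(fit_mw.params["sex_man"]) * np.exp(fit_wm.params["sex_man"])
        assert prod == pytest.approx(1.0, rel=1e-8)

    def test_separation_raises(self):
        outcome, sex = _two_by_two(0, 20, 20, 20)
        with pytest.raises(SeparationError):
            fit_logistic_cohort_adjusted(outcome, sex)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic_cohort_adjusted(
                np.ones(10), np.array(["man"] * 5 + ["woman"] * 5))

    def test_random_tables_match_closed_form(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 40, size=4)
            outcome, sex = _two_by_two(int(a), int(a + b), int(c), int(c + d))
            fit = fit_logistic_cohort_adjusted(outcome, sex)
            closed = (c / d) / (a / b)
            assert np.exp(fit.params["sex_man"]) == pytest.approx(closed, rel=1e-5)


class TestStratifiedAndInteraction:
    @staticmethod
    def _simulate(n, or_young, or_old, seed):
        rng = np.random.default_rng(seed)
        sex = np.where(rng.random(n) < 0.4, "woman", "man")
        cohort = rng.choice([f"c{i}" for i in range(3)], n)
        age = rng.uniform(40, 90, n)
        young = age < 65
        base = 0.3
        odds_w = base / (1 - base)
        or_ = np.where(young, or_young, or_old)
        odds = np.where(sex == "man", odds_w * or_, odds_w)
        p = odds / (1 + odds)
        outcome = (rng.random(n) < p).astype(int)
        return pd.DataFrame({"outcome": outcome, "sex": sex, "cohort": cohort,
                             "age": age})

    def test_stratum_or_recovery(self):
        df = add_strata(self._simulate(40_000, 1.0, 2.0, seed=5))
        res = {s.stratum: s.result.or_point
               for s in stratified_or(df, "age65")}
        assert res["<65"] == pytest.approx(1.0, abs=0.12)
        assert res[">=65"] == pytest.approx(2.0, abs=0.25)

    def test_homogeneous_strata_agree(self):
        df = add_strata(self._simulate(20_000, 1.5, 1.5, seed=6))
        ors = [s.result.or_point for s in stratified_or(df, "age65")]
        assert ors[0] == pytest.approx(ors[1], rel=0.15)

    def test_cohort_strata_pool_to_overall(self):
        # inverse-variance pooling of per-cohort ORs ~ pooled cohort-adjusted OR
        df = add_strata(self._simulate(30_000, 1.5, 1.5, seed=7))
        strata = stratified_or(df, "cohort")
        logs = np.array([np.log(s.result.or_point) for s in strata])
        ses = np.array([(np.log(s.result.ci_high) - np.log(s.result.ci_low))
                        / (2 * 1.95996) for s in strata])
        pooled = np.sum(logs / ses**2) / np.sum(1 / ses**2)
        fit = fit_logistic_cohort_adjusted(df["outcome"], df["sex"], df["cohort"])
        assert pooled == pytest.approx(fit.params["sex_man"], abs=0.02)

    def test_strong_interaction_detected(self):
        df = add_strata(self._simulate(40_000, 1.0, 3.0, seed=8))
        assert interaction_test(df, "age65") < 1e-3

    def test_no_interaction_large_p(self):
        df = add_strata(self._simulate(40_000, 1.5, 1.5, seed=9))
        assert interaction_test(df, "age65") > 0.01


class TestAgeAdjustedDifference:
    def test_no_confounding_equals_crude(self):
        rng = np.random.default_rng(10)
        n = 10_000
        sex = np.where(rng.random(n) < 0.5, "woman", "man")
        age = rng.uniform(50, 80, n)  # identical distribution in both sexes
        outcome = (rng.random(n) < np.where(sex == "woman", 0.55, 0.50)).astype(int)
        diff, lo, hi = age_adjusted_difference(outcome, sex, age)
        crude = 100 * (outcome[sex == "woman"].mean() - outcome[sex == "man"].mean())
        assert diff == pytest.approx(crude, abs=0.5)
        assert lo < diff < hi

    def test_confounded_difference_attenuates(self):
        # older patients are more often women AND more often impaired;
        # oracle: closed-form OLS on the 4-cell design
        n = 4000
        sex = np.array(["woman"] * 3000 + ["man"] * 1000
                       + ["woman"] * 1000 + ["man"] * 3000)
        age = np.array([75.0] * 4000 + [55.0] * 4000)
        p_imp = np.where(age == 75.0, 0.6, 0.4)
        rng = np.random.default_rng(11)
        outcome = (rng.random(8000) < p_imp).astype(int)
        diff, _, _ = age_adjusted_difference(outcome, sex, age)
        crude = 100 * (outcome[sex == "woman"].mean() - outcome[sex == "man"].mean())
        X = np.column_stack([np.ones(8000), sex == "woman", age])
        beta = np.linalg.lstsq(X, outcome, rcond=None)[0]
        assert diff == pytest.approx(100 * beta[1], abs=1e-6)
        assert abs(diff) < abs(crude)

    def test_equal_prevalence_near_zero(self):
        rng = np.random.default_rng(12)
        n = 20_000
        sex = np.where(rng.random(n) < 0.38, "woman", "man")
        age = rng.normal(66, 12, n)
        outcome = (rng.random(n) < 0.51).astype(int)
        diff, lo, hi = age_adjusted_difference(outcome, sex, age)
        assert abs(diff) < 3.0
        assert lo <= diff <= hi
        assert hi - lo < 6.0  # interval on the scale of a few points

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError):
            age_adjusted_difference([0, 1, 0, 1],
                                    ["woman", "woman", "man", "man"],
                                    [60, 60, 60, 60])
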