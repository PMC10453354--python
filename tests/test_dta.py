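import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

from pscikit.dta import (
    TwoByTwoTable,
    bivariate_re_meta,
    build_2x2,
    build_all_2x2,
    clopper_pearson,
    compare_sex_accuracy,
    forest_data,
    sens_spec,
    threshold_effect_check,
    univariate_re_meta,
)


def _table(tp, fp, fn, tn, cohort="c1", sex="woman", test="MMSE"):
    return TwoByTwoTable(cohort=cohort, sex=sex, test=test,
                         tp=tp, fp=fp, fn=fn, tn=tn)


class TestBuild2x2:
    @staticmethod
    def _records(rows):
        return pd.DataFrame(rows)

    def test_cutoff_boundaries(self):
        df = self._records([
            {"cohort": "c1", "sex": "woman", "psci": "present", "mmse": 24},
            {"cohort": "c1", "sex": "woman", "psci": "absent", "mmse": 25},
        ])
        t = build_2x2(df, "MMSE")
        assert (t.tp, t.tn, t.fp, t.fn) == (1, 1, 0, 0)

    def test_moca_cutoff(self):
        df = self._records([
            {"cohort": "c1", "sex": "man", "psci": "present", "moca": 25},
            {"cohort": "c1", "sex": "man", "psci": "absent", "moca": 26},
        ])
        t = build_2x2(df, "MoCA")
        assert (t.tp, t.tn) == (1, 1)

    def test_hand_tallied_stratum(self):
        rows = []
        #           psci      mmse   -> cell
        plan = [("present", 20, "tp"), ("present", 24, "tp"),
                ("present", 25, "fn"), ("present", 30, "fn"),
                ("present", 10, "tp"), ("absent", 24, "fp"),
                ("absent", 25, "tn"), ("absent", 28, "tn"),
                ("absent", 29, "tn"), ("absent", 5, "fp")]
        for psci, score, _ in plan:
            rows.append({"cohort": "c1", "sex": "woman",
                         "psci": psci, "mmse": score})
        t = build_2x2(self._records(rows), "mmse")
        tally = {"tp": 3, "fn": 2, "fp": 2, "tn": 3}
        assert (t.tp, t.fn, t.fp, t.tn) == (
            tally["tp"], tally["fn"], tally["fp"], tally["tn"])

    def test_missing_scores_excluded(self):
        df = self._records([
            {"cohort": "c1", "sex": "woman", "psci": "present", "mmse": 20},
            {"cohort": "c1", "sex": "woman", "psci": "present", "mmse": None},
        ])
        t = build_2x2(df, "MMSE")
        assert t.n_diseased == 1

    def test_indeterminate_rejected(self):
        df = self._records([
            {"cohort": "c1", "sex": "woman", "psci": "indeterminate", "mmse": 20}])
        with pytest.raises(ValueError):
            build_2x2(df, "MMSE")

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            build_2x2(pd.DataFrame(columns=["cohort", "sex", "psci", "mmse"]),
                      "MMSE")

    def test_groups_by_cohort_and_sex(self, classified_small_study):
        usable = classified_small_study[
            (classified_small_study["psci"] != "indeterminate")
            & classified_small_study["mmse"].notna()]
        tables = build_all_2x2(usable, "MMSE")
        assert tables
        total = sum(t.tp + t.fp + t.fn + t.tn for t in tables)
        assert total == len(usable)


class TestSensSpec:
    def test_definitions(self):
        s, p = sens_spec(_table(tp=9, fp=7, fn=1, tn=3))
        assert (s, p) == (0.9, 0.3)

    def test_perfect_test(self):
        assert sens_spec(_table(tp=10, fp=0, fn=0, tn=10)) == (1.0, 1.0)

    def test_paper_scale_proportions(self):
        s, p = sens_spec(_table(tp=63, fp=35, fn=37, tn=65))
        assert s == pytest.approx(0.63)
        assert p == pytest.approx(0.65)

    def test_zero_denominator_marked_nan(self):
        s, p = sens_spec(_table(tp=0, fp=5, fn=0, tn=5))
        assert np.isnan(s) and p == 0.5

    def test_label_swap_symmetry(self):
        # relabeling disease status turns sens into the complemented test's spec
        t = _table(tp=8, fp=4, fn=2, tn=6)
        swapped = _table(tp=t.fp, fp=t.tp, fn=t.tn, tn=t.fn)
        s, p = sens_spec(t)
        s2, p2 = sens_spec(swapped)
        assert s2 == pytest.approx(1 - p) and p2 == pytest.approx(1 - s)


def _brute_force_loglik(x, n, mu, tau):
    """Direct numeric integration oracle for the binomial-normal likelihood."""
    total = 0.0
    for xi, ni in zip(x, n):
        f = lambda u: (stats.binom.pmf(xi, ni, special.expit(mu + u))
                       * stats.norm.pdf(u, 0, tau))  # noqa: E731
        val, _ = integrate.quad(f, -10 * tau, 10 * tau, limit=200)
        total += np.log(val)
    return total


class TestUnivariateMeta:
    def test_single_study_reproduces_proportion(self):
        m = univariate_re_meta([53], [100])
        assert m.pooled == pytest.approx(0.53)
        assert m.tau == 0.0

    def test_identical_studies_no_heterogeneity(self):
        m = univariate_re_meta([30, 30, 30], [100, 100, 100])
        assert m.pooled == pytest.approx(0.3, abs=1e-3)
        assert m.tau == 0.0

    def test_matches_brute_force_grid(self):
        # oracle: grid maximization of the numerically integrated likelihood
        x, n = [40, 49, 56, 66], [100, 100, 100, 100]
        m = univariate_re_meta(x, n)
        best, best_ll = None, -np.inf
        for mu in np.linspace(-0.4, 0.6, 41):
            for tau in np.linspace(0.01, 1.0, 25):
                ll = _brute_force_loglik(x, n, mu, tau)
                if ll > best_ll:
                    best, best_ll = (mu, tau), ll
        assert m.mu == pytest.approx(best[0], abs=0.03)
        assert m.tau == pytest.approx(best[1], abs=0.05)
        assert m.log_likelihood >= best_ll - 1e-3

    def test_equal_n_pooled_near_mean_logit(self):
        x, n = [2000, 2450, 2800, 3300], [5000] * 4
        m = univariate_re_meta(x, n)
        expected = special.expit(np.mean(special.logit(np.array(x) / 5000)))
        assert m.pooled == pytest.approx(expected, abs=0.01)

    def test_order_invariance(self):
        a = univariate_re_meta([10, 40, 25], [50, 80, 60])
        b = univariate_re_meta([25, 10, 40], [60, 50, 80])
        assert a.pooled == pytest.approx(b.pooled, abs=1e-6)
        assert a.tau == pytest.approx(b.tau, abs=1e-6)

    def test_pooled_within_observed_range(self):
        x, n = [12, 30, 45], [60, 70, 90]
        m = univariate_re_meta(x, n)
        props = np.array(x) / np.array(n)
        assert props.min() <= m.pooled <= props.max()

    def test_node_doubling_stability(self):
        x, n = [2000, 2450, 2800, 3300], [5000] * 4
        a = univariate_re_meta(x, n, n_nodes=21)
        b = univariate_re_meta(x, n, n_nodes=42)
        assert abs(a.mu - b.mu) < 1e-4

    def test_zero_cells_handled_exactly(self):
        m = univariate_re_meta([0, 2, 5], [20, 25, 30])
        assert 0.0 < m.pooled < 0.2


class TestBivariateMeta:
    @staticmethod
    def _simulate(k, n, rho, seed, mu_s=0.8, mu_p=1.2, t_s=0.5, t_p=0.4):
        rng = np.random.default_rng(seed)
        cov = np.array([[t_s**2, rho * t_s * t_p], [rho * t_s * t_p, t_p**2]])
        u = rng.multivariate_normal([0, 0], cov, size=k)
        tp = rng.binomial(n, special.expit(mu_s + u[:, 0]))
        tn = rng.binomial(n, special.expit(mu_p + u[:, 1]))
        return [_table(tp=int(tp[i]), fp=int(n - tn[i]),
                       fn=int(n - tp[i]), tn=int(tn[i]), cohort=f"c{i}")
                for i in range(k)]

    def test_independence_matches_univariate(self):
        tables = self._simulate(8, 2000, rho=0.0, seed=1)
        biv = bivariate_re_meta(tables)
        uni_s = univariate_re_meta([t.tp for t in tables],
                                   [t.n_diseased for t in tables])
        uni_p = univariate_re_meta([t.tn for t in tables],
                                   [t.n_nondiseased for t in tables])
        assert biv.pooled_sens == pytest.approx(uni_s.pooled, abs=1e-2)
        assert biv.pooled_spec == pytest.approx(uni_p.pooled, abs=1e-2)

    def test_parameter_recovery(self):
        # moderate replication kept cheap: averages over 20 simulated panels
        k, n, rho = 12, 2000, -0.6
        est = []
        for rep in range(20):
            fit = bivariate_re_meta(self._simulate(k, n, rho, seed=100 + rep))
            est.append([fit.mu_sens, fit.mu_spec, fit.tau_sens, fit.tau_spec,
                        fit.rho])
        mean = np.mean(est, axis=0)
        mcse = np.std(est, axis=0, ddof=1) / np.sqrt(len(est))
        truth = [0.8, 1.2, 0.5, 0.4, rho]
        for m, s, t in zip(mean, mcse, truth):
            assert abs(m - t) < max(3 * s, 0.1)

    def test_no_heterogeneity_limit(self):
        tables = [_table(tp=160, fp=40, fn=40, tn=160, cohort=f"c{i}")
                  for i in range(4)]
        fit = bivariate_re_meta(tables)
        assert fit.pooled_sens == pytest.approx(0.8, abs=5e-3)
        assert fit.pooled_spec == pytest.approx(0.8, abs=5e-3)
        assert fit.tau_sens == 0.0 and fit.tau_spec == 0.0

    def test_too_few_studies_refused(self):
        with pytest.raises(ValueError, match="univariate"):
            bivariate_re_meta(self._simulate(2, 500, 0.0, seed=3))

    def test_node_refinement_stability(self):
        tables = self._simulate(6, 1000, rho=-0.4, seed=5)
        a = bivariate_re_meta(tables, n_nodes=15)
        b = bivariate_re_meta(tables, n_nodes=30)
        assert abs(a.mu_sens - b.mu_sens) < 1e-4
        assert abs(a.mu_spec - b.mu_spec) < 1e-4


class TestThresholdEffect:
    def test_common_roc_curve_shows_evidence(self):
        # five operating points along one logistic ROC curve
        fpr = np.array([0.05, 0.15, 0.3, 0.5, 0.7])
        sens = special.expit(1.0 + special.logit(fpr))
        verdict, rho, _ = threshold_effect_check(
            pd.DataFrame({"sens": sens, "fpr": fpr}))
        assert verdict == "evidence"
        assert rho == pytest.approx(1.0)

    def test_varying_prevalence_only_no_evidence(self):
        pts = pd.DataFrame({"sens": [0.8, 0.8, 0.8], "spec": [0.7, 0.7, 0.7]})
        verdict, rho, _ = threshold_effect_check(pts)
        assert verdict == "little_evidence"
        assert rho == 0.0

    def test_antitonic_points(self):
        pts = pd.DataFrame({"sens": [0.9, 0.8, 0.7], "fpr": [0.1, 0.2, 0.3]})
        verdict, rho, _ = threshold_effect_check(pts)
        assert rho == pytest.approx(-1.0)
        assert verdict == "little_evidence"


class TestSexComparison:
    def test_identical_data_null(self):
        tw = [_table(tp=50, fp=20, fn=50, tn=80, cohort=f"c{i}")
              for i in range(3)]
        tm = [_table(tp=50, fp=20, fn=50, tn=80, cohort=f"c{i}", sex="man")
              for i in range(3)]
        res = compare_sex_accuracy(tw, tm, "sens")
        assert abs(res.beta_sex) < 1e-4
        assert res.p_value > 0.95

    def test_power_at_reported_effect(self):
        # women sens 0.53 vs men 0.27, 4 cohorts x 500/arm: detected in
        # at least 90% of replicates
        rng = np.random.default_rng(7)
        hits = 0
        reps = 40
        for _ in range(reps):
            xw = rng.binomial(500, 0.53, size=4)
            xm = rng.binomial(500, 0.27, size=4)
            tw = [_table(tp=int(x), fp=10, fn=int(500 - x), tn=10,
                         cohort=f"c{i}") for i, x in enumerate(xw)]
            tm = [_table(tp=int(x), fp=10, fn=int(500 - x), tn=10,
                         cohort=f"c{i}", sex="man") for i, x in enumerate(xm)]
            if compare_sex_accuracy(tw, tm, "sens").p_value < 0.05:
                hits += 1
        assert hits / reps >= 0.9

    def test_pooled_estimates_per_sex(self):
        tw = [_table(tp=400, fp=10, fn=100, tn=10, cohort=f"c{i}")
              for i in range(3)]
        tm = [_table(tp=100, fp=10, fn=400, tn=10, cohort=f"c{i}", sex="man")
              for i in range(3)]
        res = compare_sex_accuracy(tw, tm, "sens")
        assert res.pooled_women == pytest.approx(0.8, abs=0.02)
        assert res.pooled_men == pytest.approx(0.2, abs=0.02)
        assert res.p_value < 1e-4


class TestForestData:
    def test_clopper_pearson_extremes(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-9)
        assert hi == pytest.approx(0.308, abs=1e-3)
        lo2, hi2 = clopper_pearson(10, 10)
        assert (lo2, hi2) == (pytest.approx(1 - hi, abs=1e-9), 1.0)

    def test_pooled_row_matches_meta(self):
        tables = [_table(tp=40, fp=10, fn=60, tn=90, cohort=f"c{i}")
                  for i in range(3)]
        df = forest_data(tables, "sens")
        meta = univariate_re_meta([40] * 3, [100] * 3)
        pooled = df[df["pooled"]].iloc[0]
        assert pooled["proportion"] == pytest.approx(meta.pooled, abs=1e-9)
        assert len(df) == 4
        study_rows = df[~df["pooled"]]
        assert (study_rows["ci_low"] <= study_rows["proportion"]).all()
        assert (study_rows["ci_high"] >= study_rows["proportion"]).all()
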