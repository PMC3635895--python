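import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from oracles import cox_partial_loglik, km_survival, logrank_chi2, welch_t

from invasig.clinical import (
    compare_groups,
    control_cohort_run,
    cox_multivariate,
    km_curve,
    km_logrank,
    logrank_test,
    remove_overlap_and_retest,
)
from invasig.datatypes import CohortTable
from invasig.simulate import simulate_survival_cohort


def _series(values, prefix="s"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))], dtype=float)


def _labels(n_a, n_b):
    return pd.Series(
        ["sensitive"] * n_a + ["resistant"] * n_b,
        index=[f"s{i}" for i in range(n_a + n_b)],
    )


class TestCompareGroups:
    def test_identical_groups_t_zero(self):
        scores = _series([1, 2, 3, 1, 2, 3])
        res = compare_groups(scores, _labels(3, 3))
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_separated_groups_significant(self, rng):
        scores = _series(
            np.concatenate([rng.normal(0, 0.01, 4), rng.normal(1, 0.01, 4)])
        )
        res = compare_groups(scores, _labels(4, 4))
        assert res.p_two_sided < 0.01

    def test_welch_formula_oracle(self, rng):
        for _ in range(50):
            a = rng.normal(size=int(rng.integers(3, 12)))
            b = rng.normal(2, 3, size=int(rng.integers(3, 12)))
            scores = _series(np.concatenate([a, b]))
            res = compare_groups(scores, _labels(len(a), len(b)), welch=True)
            # labels sort as (resistant, sensitive): oracle order must match
            t_oracle, df_oracle = welch_t(b, a)
            assert res.t_statistic == pytest.approx(t_oracle, abs=1e-10)
            p_oracle = 2 * stats.t.sf(abs(t_oracle), df_oracle)
            assert res.p_two_sided == pytest.approx(p_oracle, abs=1e-10)

    def test_group_too_small_errors(self):
        scores = _series([1, 2, 3])
        with pytest.raises(ValueError, match=">= 2"):
            compare_groups(scores, _labels(1, 2))

    def test_pooled_variant_matches_scipy(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=9)
        scores = _series(np.concatenate([a, b]))
        res = compare_groups(scores, _labels(6, 9), welch=False)
        expected = stats.ttest_ind(b, a, equal_var=True)
        assert res.t_statistic == pytest.approx(expected.statistic)


class TestRemoveOverlap:
    def test_empty_exclusion_identity(self, rng):
        scores = _series(rng.normal(size=10))
        labels = _labels(5, 5)
        a = compare_groups(scores, labels)
        b = remove_overlap_and_retest(scores, labels, [])
        assert a == b

    def test_excluding_whole_group_errors(self):
        scores = _series([1, 2, 3, 4])
        labels = _labels(2, 2)
        with pytest.raises(ValueError):
            remove_overlap_and_retest(scores, labels, ["s0", "s1"])

    def test_excluding_null_members_small_p_change(self, rng):
        # removing a few exchangeable samples only perturbs p moderately
        deltas = []
        for rep in range(40):
            r = np.random.default_rng(rep)
            scores = _series(np.concatenate([r.normal(0, 1, 15), r.normal(1.5, 1, 15)]))
            labels = _labels(15, 15)
            full = compare_groups(scores, labels)
            reduced = remove_overlap_and_retest(scores, labels, ["s0", "s16"])
            deltas.append(abs(full.p_two_sided - reduced.p_two_sided))
        assert np.median(deltas) < 0.05


class TestKm:
    def test_three_events_hand_curve(self):
        curve = km_curve([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(curve["survival"], [2 / 3, 1 / 3, 0.0])

    def test_no_censoring_matches_empirical_survival(self, rng):
        for _ in range(20):
            times = rng.exponential(10, size=int(rng.integers(5, 20)))
            curve = km_curve(times, np.ones(len(times), dtype=int))
            oracle = km_survival(list(times), [1] * len(times))
            np.testing.assert_allclose(curve["survival"], [s for _, s in oracle], atol=1e-12)
            # empirical survival function at each event time
            for t, s in oracle:
                assert s == pytest.approx(np.mean(times > t))

    def test_censoring_reduces_risk_set_not_curve_steps(self):
        curve = km_curve([1.0, 2.0, 3.0], [1, 0, 1])
        np.testing.assert_allclose(curve["survival"], [2 / 3, 0.0])


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1, 1, 1, 1, 1, 1]
        groups = list("aaabbb")
        chi2, p = logrank_test(times, events, groups)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_six_subject_oracle(self):
        times = [1.0, 3.0, 5.0, 2.0, 4.0, 6.0]
        events = [1, 1, 0, 1, 1, 1]
        groups = list("aaabbb")
        chi2, _ = logrank_test(times, events, groups)
        assert chi2 == pytest.approx(logrank_chi2(times, events, groups), abs=1e-10)

    def test_random_instances_match_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 25))
            times = np.round(rng.exponential(10, n), 1)
            events = rng.integers(0, 2, n)
            groups = rng.choice(["a", "b"], n)
            if events.sum() == 0 or len(set(groups)) < 2:
                continue
            chi2, _ = logrank_test(times, events, groups)
            assert chi2 == pytest.approx(
                logrank_chi2(list(times), list(events), list(groups)), abs=1e-10
            )

    def test_null_permutation_uniform(self, rng):
        # permuting labels under the null gives uniform p values
        n = 40
        times = rng.exponential(10, n)
        events = rng.integers(0, 2, n)
        events[0] = 1
        ps = []
        for _ in range(300):
            groups = rng.permutation(["a"] * 20 + ["b"] * 20)
            _, p = logrank_test(times, events, groups)
            ps.append(p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


def _cohort(times, events, extra=None, genes=()):
    data = pd.DataFrame(
        {"time": times, "event": events},
        index=pd.Index([f"p{i}" for i in range(len(times))], name="patient_id"),
    )
    for k, v in (extra or {}).items():
        data[k] = v
    return CohortTable(data, gene_cols=genes, covariate_cols=tuple((extra or {}).keys()))


class TestKmLogrank:
    def test_report_structure(self):
        cohort = _cohort([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 0])
        groups = pd.Series(list("hhhlll"), index=cohort.data.index)
        report = km_logrank(cohort, groups)
        assert set(report.km) == {"h", "l"}
        for curve in report.km.values():
            assert (np.diff(curve["survival"]) <= 1e-12).all()
        assert report.logrank_chi2 >= 0

    def test_zero_event_group_warns_but_runs(self, caplog):
        cohort = _cohort([1, 2, 3, 4], [1, 1, 0, 0])
        groups = pd.Series(list("aabb"), index=cohort.data.index)
        report = km_logrank(cohort, groups)
        assert math.isfinite(report.logrank_chi2)


class TestCox:
    def test_null_binary_covariate(self):
        # identical event patterns in both levels -> coefficient ~ 0
        times = [1, 2, 3, 4, 5, 6, 1, 2, 3, 4, 5, 6]
        events = [1] * 12
        x = [0] * 6 + [1] * 6
        cohort = _cohort(times, events, {"x": x})
        res = cox_multivariate(cohort, ["x"])
        assert res.converged
        assert res.summary.loc["x", "coef"] == pytest.approx(0.0, abs=0.05)
        assert res.summary.loc["x", "hr"] == pytest.approx(1.0, abs=0.06)

    def test_grid_search_oracle_no_ties(self):
        # explicit partial-likelihood maximization for one binary covariate
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        events = [1, 1, 1, 1, 1, 1, 1, 0, 1, 1]
        x = [1, 0, 1, 0, 1, 1, 0, 0, 0, 0]
        cohort = _cohort(times, events, {"x": x})
        res = cox_multivariate(cohort, ["x"])
        opt = minimize_scalar(
            lambda b: -cox_partial_loglik(b, times, events, x), bounds=(-5, 5), method="bounded"
        )
        assert res.summary.loc["x", "coef"] == pytest.approx(opt.x, abs=1e-4)

    def test_parameter_recovery(self):
        cohort = simulate_survival_cohort(2000, math.log(2.0), censoring_rate=0.2, seed=11)
        res = cox_multivariate(cohort, ["true_score"])
        assert res.summary.loc["true_score", "coef"] == pytest.approx(math.log(2.0), abs=0.1)

    def test_hr_is_exp_coef_and_ci_ordered(self):
        cohort = simulate_survival_cohort(300, 0.5, seed=3)
        res = cox_multivariate(cohort, ["true_score", "age"])
        s = res.summary
        np.testing.assert_allclose(s["hr"], np.exp(s["coef"]))
        assert (s["ci_low"] <= s["hr"]).all() and (s["hr"] <= s["ci_high"]).all()

    def test_constant_covariate_errors(self):
        cohort = _cohort([1, 2, 3, 4, 5, 6, 7, 8], [1] * 8, {"x": [1] * 8})
        with pytest.raises(ValueError, match="constant"):
            cox_multivariate(cohort, ["x"])

    def test_too_few_events_errors(self):
        cohort = _cohort([1, 2, 3, 4], [1, 1, 0, 0], {"x": [0, 1, 0, 1]})
        with pytest.raises(ValueError, match="events"):
            cox_multivariate(cohort, ["x"])

    def test_score_test_direction_agrees_with_logrank(self, rng):
        # single binary covariate, no ties: Cox sign agrees with log-rank
        for rep in range(5):
            r = np.random.default_rng(rep)
            n = 60
            x = r.integers(0, 2, n)
            times = r.exponential(np.where(x == 1, 5, 10))
            times += r.uniform(0, 1e-6, n)  # break ties
            cohort = _cohort(times, [1] * n, {"x": x})
            res = cox_multivariate(cohort, ["x"])
            chi2, _ = logrank_test(times, [1] * n, x)
            assert res.summary.loc["x", "coef"] > 0  # x=1 has higher hazard
            assert chi2 > 0


class TestControlCohorts:
    def test_treated_vs_control_split(self):
        hits_treated = hits_control = 0
        reps = 25
        for rep in range(reps):
            treated = simulate_survival_cohort(200, math.log(2.5), seed=rep)
            control = simulate_survival_cohort(200, 0.0, seed=10_000 + rep)
            cohorts = {"treated": (treated, True), "control": (control, False)}
            groups = {
                name: pd.Series(
                    np.where(c.data["true_score"] > c.data["true_score"].mean(), "high", "low"),
                    index=c.data.index,
                )
                for name, (c, _) in cohorts.items()
            }
            _, summary = control_cohort_run(cohorts, groups)
            p = summary.set_index("cohort")["logrank_p"]
            if p["treated"] < 0.05:
                hits_treated += 1
            if p["control"] < 0.05:
                hits_control += 1
        assert hits_treated >= 0.8 * reps
        assert hits_control <= 0.2 * reps

    def test_single_cohort_summary_length_one(self):
        c = simulate_survival_cohort(100, 0.5, seed=1)
        groups = {
            "only": pd.Series(
                np.where(c.data["true_score"] > 0, "high", "low"), index=c.data.index
            )
        }
        _, summary = control_cohort_run({"only": (c, True)}, groups)
        assert len(summary) == 1

    def test_all_censored_cohort_flagged_not_fatal(self):
        data = pd.DataFrame(
            {"time": [5.0, 6.0, 7.0, 8.0], "event": [0, 0, 0, 0]},
            index=pd.Index([f"p{i}" for i in range(4)], name="patient_id"),
        )
        dead = CohortTable(data)
        ok = simulate_survival_cohort(100, 0.5, seed=2)
        groups = {
            "dead": pd.Series(list("hhll"), index=dead.data.index),
            "ok": pd.Series(np.where(ok.data["true_score"] > 0, "high", "low"), index=ok.data.index),
        }
        reports, summary = control_cohort_run({"dead": (dead, False), "ok": (ok, True)}, groups)
        assert "dead" not in reports and "ok" in reports
        row = summary.set_index("cohort").loc["dead"]
        assert row["status"].startswith("skipped")
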