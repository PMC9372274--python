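"""Kaplan-Meier, log-rank, Cox regression and variable selection."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from phenoclust import (
    Cohort,
    PatientProfile,
    build_survival_frame,
    cox_fit,
    km_estimate,
    logrank_test,
    multivariate_cox,
    select_variables,
    univariate_cox_screen,
)
from phenoclust.clustering import ClusterAssignment
from phenoclust.simulate import simulate_proportional_hazards

from oracles import cox_partial_loglik_no_ties, product_limit, two_group_logrank_oe


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        curve = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert curve.times.size == 0
        assert curve.survival_at(100.0) == 1.0

    def test_closed_form_one_death(self):
        curve = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 0, 0, 0])
        assert curve.survival_at(1.0) == pytest.approx(0.75)
        assert curve.at_risk.tolist() == [4]

    def test_mixed_fixture_matches_product_limit_oracle(self):
        times = [1.0, 1.0, 2.0, 3.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        events = [1, 0, 1, 1, 1, 0, 1, 0, 1, 0]
        curve = km_estimate(times, events)
        oracle = product_limit(times, events)
        assert curve.times.tolist() == [t for t, _ in oracle]
        assert curve.survival == pytest.approx([s for _, s in oracle], abs=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(5, 30)
        events = rng.integers(0, 2, 30)
        a = km_estimate(times, events)
        perm = rng.permutation(30)
        b = km_estimate(times[perm], events[perm])
        assert a.survival == pytest.approx(b.survival, abs=1e-15)

    def test_censor_tied_with_death_handled_events_first(self):
        # at t=2 one death and one censoring: censored subject still at risk
        curve = km_estimate([2.0, 2.0, 3.0], [1, 0, 1])
        assert curve.at_risk.tolist() == [3, 1]
        assert curve.survival == pytest.approx([2 / 3, 0.0])

    def test_median(self):
        curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert curve.median == 2.0


class TestLogrank:
    def test_mirrored_groups_statistic_zero(self):
        times = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        events = [1, 0, 1, 1, 0, 1, 0, 1, 1, 0]
        groups = [0] * 5 + [1] * 5
        chi2, df, p = logrank_test(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(5, 60)
        events = rng.integers(0, 2, 60)
        groups = rng.integers(0, 3, 60)
        a = logrank_test(times, events, groups)[0]
        b = logrank_test(times, events, 2 - groups)[0]
        assert a == pytest.approx(b, abs=1e-10)

    def test_two_group_equals_squared_standardised_oe(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(5, 80)
        groups = rng.integers(0, 2, 80)
        times[groups == 1] *= 0.5
        events = (rng.random(80) < 0.8).astype(int)
        chi2, df, _ = logrank_test(times, events, groups)
        O, E, V = two_group_logrank_oe(times, events, groups)
        assert chi2 == pytest.approx((O - E) ** 2 / V, rel=1e-9)

    def test_zero_events_error(self):
        with pytest.raises(ValueError, match="zero events"):
            logrank_test([1, 2], [0, 0], [0, 1])

    def test_single_group_error(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestCoxFit:
    def test_null_covariate_recovered_within_three_se(self):
        rng = np.random.default_rng(10)
        x, time, event = simulate_proportional_hazards(500, 0.0, rng)
        res = cox_fit(x.reshape(-1, 1), time, event)
        row = res.table.iloc[0]
        assert abs(row["coef"]) < 3 * row["se"]

    def test_partial_likelihood_matches_grid_search_oracle(self):
        rng = np.random.default_rng(11)
        x, time, event = simulate_proportional_hazards(60, np.log(2), rng)
        res = cox_fit(x.reshape(-1, 1), time, event)
        beta_hat = res.table["coef"].iloc[0]
        neg = lambda b: -cox_partial_loglik_no_ties(b, x, time, event)
        oracle = optimize.minimize_scalar(neg, bounds=(-4, 4), method="bounded")
        assert abs(
            cox_partial_loglik_no_ties(beta_hat, x, time, event) - (-oracle.fun)
        ) < 1e-6
        assert beta_hat == pytest.approx(oracle.x, abs=1e-4)

    def test_exact_risk_set_enumeration_small_n(self):
        # n <= 12, no ties: maximise the literal risk-set product directly
        rng = np.random.default_rng(12)
        for _ in range(5):
            x = rng.integers(0, 2, 10).astype(float)
            if x.min() == x.max():
                continue
            time = rng.exponential(1, 10)
            event = np.ones(10, dtype=int)
            event[rng.integers(0, 10)] = 0
            res = cox_fit(x.reshape(-1, 1), time, event)
            neg = lambda b: -cox_partial_loglik_no_ties(b, x, time, event)
            oracle = optimize.minimize_scalar(neg, bounds=(-8, 8), method="bounded")
            assert res.table["coef"].iloc[0] == pytest.approx(oracle.x, abs=1e-3)

    def test_agrees_with_lifelines_including_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(13)
        n = 300
        X = np.column_stack([rng.integers(0, 2, n), rng.normal(size=n)])
        beta = np.array([np.log(2), -0.4])
        t_event = rng.exponential(1 / (0.1 * np.exp(X @ beta)))
        t_cens = rng.uniform(0, 20, n)
        time = np.ceil(np.minimum(t_event, t_cens))  # heavy ties
        event = (t_event <= t_cens).astype(int)
        mine = cox_fit(X, time, event, names=["a", "b"], ties="efron")
        df = pd.DataFrame({"a": X[:, 0], "b": X[:, 1], "T": time, "E": event})
        ll = CoxPHFitter().fit(df, "T", "E")
        assert mine.table["coef"].to_numpy() == pytest.approx(
            ll.params_.to_numpy(), abs=1e-5
        )
        assert mine.table["se"].to_numpy() == pytest.approx(
            ll.standard_errors_.to_numpy(), abs=1e-5
        )

    def test_breslow_option_differs_under_ties(self):
        rng = np.random.default_rng(14)
        x, time, event = simulate_proportional_hazards(200, np.log(2), rng)
        time = np.ceil(time)
        efron = cox_fit(x.reshape(-1, 1), time, event, ties="efron")
        breslow = cox_fit(x.reshape(-1, 1), time, event, ties="breslow")
        assert efron.table["coef"].iloc[0] != breslow.table["coef"].iloc[0]

    def test_parameter_recovery_short(self):
        rng = np.random.default_rng(15)
        estimates = []
        for _ in range(30):
            x, time, event = simulate_proportional_hazards(1000, np.log(2), rng)
            estimates.append(
                cox_fit(x.reshape(-1, 1), time, event).table["coef"].iloc[0]
            )
        assert abs(np.mean(estimates) - np.log(2)) < 0.05

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(np.ones((10, 1)), np.arange(1, 11), np.ones(10, dtype=int))

    def test_ci_brackets_hr(self):
        rng = np.random.default_rng(16)
        x, time, event = simulate_proportional_hazards(300, np.log(2), rng)
        res = cox_fit(x.reshape(-1, 1), time, event)
        row = res.table.iloc[0]
        assert row["ci_low"] < row["hr"] < row["ci_high"]
        assert row["hr"] == pytest.approx(np.exp(row["coef"]))
        assert row["ci_high"] == pytest.approx(
            np.exp(row["coef"] + 1.959963984540054 * row["se"])
        )


def selection_cohort(toy_dag):
    """60 patients: term C at 30%, D at 4%, E at 100% (base), F at 10%."""
    rng = np.random.default_rng(20)
    profiles, labels = [], {}
    for i in range(60):
        terms = {"E"}
        if i < 18:
            terms.add("C")  # 30%
        if i < 2:
            terms.add("D")  # ~3.3%
        if i % 10 == 0:
            terms.add("F")  # 10%
        pid = f"s{i}"
        profiles.append(
            PatientProfile(
                pid,
                frozenset(terms),
                age_at_surgery=float(rng.uniform(0.5, 10)),
                sex="female" if i % 2 else "male",
                bmi=float(rng.normal(16, 2)),
                family_history=False,
                surgery="repair" if i % 3 else "shunts",
                time=float(rng.exponential(5) + 0.01),
                event=int(rng.random() < 0.5),
            )
        )
        labels[pid] = 1 if i < 40 else (2 if i < 55 else 3)
    cohort = Cohort(profiles, toy_dag)
    assignment = ClusterAssignment(k=3, labels=labels, sizes=[40, 15, 5])
    return cohort, assignment


class TestSelectVariables:
    def test_univariate_prevalence_screen(self, toy_dag):
        cohort, assignment = selection_cohort(toy_dag)
        selected = select_variables(cohort, assignment, "univariate")
        assert "term_C" in selected  # 30% > 5%
        assert "term_F" in selected  # 10% > 5%
        assert "term_D" not in selected  # ~3% excluded
        assert "cluster" in selected and "age_at_surgery" in selected

    def test_multivariate_rules(self, toy_dag):
        cohort, assignment = selection_cohort(toy_dag)
        uni = pd.DataFrame(
            {"p": [0.01, 0.30, 0.04]},
            index=pd.Index(["term_D", "term_F", "cluster"], name="variable"),
        )
        selected = select_variables(
            cohort, assignment, "multivariate", univariate_results=uni
        )
        assert "term_C" in selected      # prevalence 30% > 25%, p irrelevant
        assert "term_D" in selected      # significant univariate, rare
        assert "term_F" not in selected  # 10% < 25% and p = 0.3
        assert "cluster_1" in selected and "cluster_2" in selected
        assert "cluster" not in selected  # ordinal replaced by dummies

    def test_multivariate_needs_univariate(self, toy_dag):
        cohort, assignment = selection_cohort(toy_dag)
        with pytest.raises(ValueError):
            select_variables(cohort, assignment, "multivariate")


class TestCohortLevel:
    def test_build_frame_encodings(self, toy_dag):
        cohort, assignment = selection_cohort(toy_dag)
        df = build_survival_frame(cohort, assignment)
        assert set(df["cluster"].unique()) == {1.0, 2.0, 3.0}
        # smallest cluster (3) is the dummy reference
        assert "cluster_1" in df.columns and "cluster_2" in df.columns
        assert "cluster_3" not in df.columns
        assert df.loc["s1", "sex"] == 1.0  # odd index -> female

    def test_univariate_screen_and_multivariate_run(self, toy_dag):
        cohort, assignment = selection_cohort(toy_dag)
        df = build_survival_frame(cohort, assignment)
        variables = select_variables(cohort, assignment, "univariate")
        uni = univariate_cox_screen(df, variables)
        assert {"coef", "hr", "ci_low", "ci_high", "p"} <= set(uni.columns)
        multi_vars = select_variables(
            cohort, assignment, "multivariate", univariate_results=uni
        )
        res = multivariate_cox(df, multi_vars)
        assert res.model == "multivariate"
        assert len(res.table) >= 2
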