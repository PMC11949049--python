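"""Tests of the Kaplan-Meier estimator, log-rank test and Cox regression
against independent reference implementations (lifelines) and oracles."""

import numpy as np
import pandas as pd
import pytest

from consensusdeg import survival

from _oracles import logrank_chi2_bruteforce


def random_survival(rng, n=60, censor_frac=0.3):
    times = rng.exponential(100, n).round(1) + 0.1
    events = (rng.uniform(size=n) > censor_frac).astype(int)
    return pd.DataFrame(
        {"time": times, "event": events},
        index=[f"s{i}" for i in range(n)],
    )


class TestKaplanMeier:
    def test_distinct_event_times_drop_by_one_over_n(self):
        km = survival.kaplan_meier([1, 2, 3, 4], [1, 1, 1, 1])
        np.testing.assert_allclose(km["survival"], [0.75, 0.5, 0.25, 0.0])
        np.testing.assert_allclose(km["n_risk"], [4, 3, 2, 1])

    def test_no_events_curve_stays_at_one(self):
        km = survival.kaplan_meier([5, 6, 7], [0, 0, 0])
        assert len(km) == 0  # no drops: S(t) = 1 everywhere

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        surv = random_survival(rng, n=80)
        km = survival.kaplan_meier(surv["time"].to_numpy(),
                                   surv["event"].to_numpy())
        kmf = KaplanMeierFitter().fit(surv["time"], surv["event"])
        for _, row in km.iterrows():
            ref = float(kmf.survival_function_at_times(row["time"]).iloc[0])
            assert row["survival"] == pytest.approx(ref, rel=1e-10)

    def test_median_split_groups_and_curves(self, rng):
        surv = random_survival(rng, n=40)
        expr = pd.Series(rng.normal(size=40), index=surv.index)
        labels, curves = survival.km_median_split(expr, surv)
        assert set(labels.unique()) == {"high", "low"}
        assert set(curves) == {"high", "low"}
        assert (labels == "high").sum() == 20


class TestLogrank:
    def test_identical_groups_give_zero_chi2(self):
        times = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        events = [1] * 10
        surv = pd.DataFrame({"time": times, "event": events},
                            index=[f"s{i}" for i in range(10)])
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=surv.index)
        chi2, p = survival.logrank_test(labels, surv)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_group_swap_invariance(self, rng):
        surv = random_survival(rng)
        labels = pd.Series(rng.choice(["a", "b"], size=len(surv)),
                           index=surv.index)
        if labels.nunique() < 2:
            labels.iloc[0] = "a" if labels.iloc[0] == "b" else "b"
        c1, p1 = survival.logrank_test(labels, surv)
        swapped = labels.map({"a": "b", "b": "a"})
        c2, p2 = survival.logrank_test(swapped, surv)
        assert c1 == pytest.approx(c2, rel=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        for _ in range(5):
            surv = random_survival(rng, n=50)
            labels = pd.Series(rng.choice(["a", "b"], size=50), index=surv.index)
            mask = labels == "a"
            if mask.sum() < 2 or (~mask).sum() < 2:
                continue
            chi2, p = survival.logrank_test(labels, surv)
            ref = ll_logrank(
                surv.loc[mask, "time"], surv.loc[~mask, "time"],
                surv.loc[mask, "event"], surv.loc[~mask, "event"],
            )
            assert chi2 == pytest.approx(ref.test_statistic, rel=1e-8)
            assert p == pytest.approx(ref.p_value, rel=1e-8)

    def test_matches_independent_bruteforce(self, rng):
        surv = random_survival(rng, n=30)
        labels = pd.Series(["a"] * 15 + ["b"] * 15, index=surv.index)
        chi2, _ = survival.logrank_test(labels, surv)
        ref = logrank_chi2_bruteforce(
            surv["time"], surv["event"], (labels == "a").to_numpy()
        )
        assert chi2 == pytest.approx(ref, rel=1e-12)

    def test_monotone_expression_transform_leaves_p_unchanged(self, rng):
        surv = random_survival(rng, n=40)
        expr = pd.Series(rng.normal(size=40), index=surv.index)
        labels1, _ = survival.km_median_split(expr, surv)
        labels2, _ = survival.km_median_split(np.exp(expr / 2), surv)
        pd.testing.assert_series_equal(labels1, labels2, check_names=False)

    def test_zero_events_rejected(self):
        surv = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0], "event": [0] * 4},
                            index=list("abcd"))
        labels = pd.Series(["a", "a", "b", "b"], index=surv.index)
        with pytest.raises(ValueError, match="zero events"):
            survival.logrank_test(labels, surv)

    def test_strong_separation_detected(self, rng):
        """Hazard ratio 3 at n=100: essentially always p < 0.001."""
        hits = 0
        reps = 20
        for r in range(reps):
            local = np.random.default_rng(1000 + r)
            x = np.repeat([0.0, 1.0], 50)
            times = local.exponential(1.0 / np.exp(np.log(3.0) * x))
            surv = pd.DataFrame(
                {"time": times, "event": 1},
                index=[f"s{i}" for i in range(100)],
            )
            labels = pd.Series(np.where(x > 0, "high", "low"), index=surv.index)
            _, p = survival.logrank_test(labels, surv)
            hits += p < 0.001
        assert hits >= int(0.9 * reps)

    def test_null_type_one_error_calibrated(self):
        """Empirical size of the log-rank test near the nominal 5% level."""
        rejections = 0
        reps = 1000
        rng = np.random.default_rng(77)
        for _ in range(reps):
            times = rng.exponential(1.0, 40)
            events = (rng.uniform(size=40) > 0.2).astype(int)
            if events.sum() == 0:
                continue
            surv = pd.DataFrame({"time": times, "event": events},
                                index=[f"s{i}" for i in range(40)])
            labels = pd.Series(["a"] * 20 + ["b"] * 20, index=surv.index)
            _, p = survival.logrank_test(labels, surv)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestCox:
    def test_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter

        n = 120
        x = rng.normal(size=n)
        times = rng.exponential(1.0 / np.exp(0.6 * x))
        events = (rng.uniform(size=n) > 0.25).astype(int)
        surv = pd.DataFrame({"time": times, "event": events},
                            index=[f"s{i}" for i in range(n)])
        expr = pd.Series(x, index=surv.index)
        fit = survival.cox_univariate(expr, surv)
        df = surv.assign(x=x)
        cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
        assert fit["beta"] == pytest.approx(cph.params_["x"], rel=1e-5)
        assert fit["se"] == pytest.approx(cph.standard_errors_["x"], rel=1e-4)
        assert fit["hazard_ratio"] == pytest.approx(np.exp(fit["beta"]))

    def test_beta_scales_inversely_with_units(self, rng):
        n = 80
        x = rng.normal(size=n)
        times = rng.exponential(1.0 / np.exp(0.5 * x))
        surv = pd.DataFrame({"time": times, "event": 1},
                            index=[f"s{i}" for i in range(n)])
        f1 = survival.cox_univariate(pd.Series(x, index=surv.index), surv)
        f2 = survival.cox_univariate(pd.Series(2.0 * x, index=surv.index), surv)
        assert f2["beta"] == pytest.approx(f1["beta"] / 2.0, rel=1e-6)
        assert f2["wald_p"] == pytest.approx(f1["wald_p"], rel=1e-6)

    def test_score_test_equals_logrank_for_binary_covariate(self, rng):
        """Cox score chi2 at beta=0 equals the log-rank statistic when event
        times are distinct (hypergeometric variance factor is then 1)."""
        n = 50
        x = rng.permutation(np.repeat([0.0, 1.0], 25))
        times = rng.exponential(1.0, n)  # continuous: ties a.s. absent
        surv = pd.DataFrame({"time": times, "event": 1},
                            index=[f"s{i}" for i in range(n)])
        expr = pd.Series(x, index=surv.index)
        labels = pd.Series(np.where(x > 0, "a", "b"), index=surv.index)
        chi2_lr, _ = survival.logrank_test(labels, surv)
        chi2_score = survival.cox_score_test(expr, surv)
        assert chi2_score == pytest.approx(chi2_lr, abs=1e-6)

    def test_validation_errors(self, rng):
        surv = random_survival(rng, n=20)
        const = pd.Series(1.0, index=surv.index)
        with pytest.raises(ValueError, match="constant"):
            survival.cox_univariate(const, surv)
        small = surv.iloc[:5]
        with pytest.raises(ValueError, match=">=10"):
            survival.cox_univariate(pd.Series(rng.normal(size=5),
                                              index=small.index), small)

    def test_perfect_separation_raises_with_trace(self):
        n = 20
        x = np.arange(n, dtype=float)
        # hazard so strongly ordered that the likelihood is monotone in beta
        times = np.sort(np.arange(1, n + 1, dtype=float))[::-1]
        surv = pd.DataFrame({"time": times, "event": 1},
                            index=[f"s{i}" for i in range(n)])
        with pytest.raises(survival.CoxConvergenceError) as err:
            survival.cox_univariate(pd.Series(x, index=surv.index), surv)
        assert err.value.trace  # iteration trace attached


class TestMultiCohortSummary:
    def _cohort_tables(self, rng, betas, n=120):
        tables = []
        for i, beta in enumerate(betas):
            x = rng.normal(size=n)
            times = rng.exponential(1.0 / np.exp(beta * x))
            events = (rng.uniform(size=n) > 0.2).astype(int)
            tables.append(
                (
                    f"c{i}",
                    pd.DataFrame(
                        {"time": times, "event": events, "GENE": x},
                        index=[f"c{i}s{j}" for j in range(n)],
                    ),
                )
            )
        return tables

    def test_all_cohort_flag_for_strong_gene(self, rng):
        tables = self._cohort_tables(rng, [1.2, 1.2, 1.2, 1.2], n=200)
        summ = survival.multi_cohort_summary("GENE", tables)
        assert summ.n_significant == 4
        assert summ.n_worse_when_high == 4
        assert summ.flagged_all_cohorts and summ.flagged_min_count

    def test_null_gene_collects_no_flags(self, rng):
        tables = self._cohort_tables(rng, [0.0, 0.0, 0.0], n=60)
        summ = survival.multi_cohort_summary("GENE", tables)
        assert not summ.flagged_min_count
        assert summ.n_significant <= 1  # chance-level at alpha 0.05

    def test_counts_equal_bruteforce_recount(self, rng):
        tables = self._cohort_tables(rng, [0.8, 0.0, 0.8, 0.0], n=150)
        summ = survival.multi_cohort_summary("GENE", tables)
        n_sig = n_high = n_low = 0
        for _, row in summ.per_cohort.iterrows():
            if row["km_p"] < 0.05:
                n_sig += 1
                if row["direction"] == "worse_when_high":
                    n_high += 1
                else:
                    n_low += 1
        assert (summ.n_significant, summ.n_worse_when_high,
                summ.n_worse_when_low) == (n_sig, n_high, n_low)

    def test_missing_gene_recorded_not_raised(self, rng):
        tables = self._cohort_tables(rng, [0.8], n=100)
        tables.append(("empty", pd.DataFrame(
            {"time": [1.0] * 12, "event": [1] * 12},
            index=[f"e{i}" for i in range(12)],
        )))
        summ = survival.multi_cohort_summary("GENE", tables)
        assert len(summ.per_cohort) == 1

    def test_empty_cohort_list_rejected(self):
        with pytest.raises(ValueError):
            survival.multi_cohort_summary("GENE", [])
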