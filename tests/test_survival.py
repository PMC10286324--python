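import numpy as np
import pytest

from fusionburden.simulate import SurvivalSimSpec, simulate_survival
from fusionburden.summary import BurdenTable
from fusionburden.survival import (
    GroupingSpec,
    _cox_derivatives,
    assign_groups,
    cox_fit,
    km_fit,
    logrank,
)


class TestKaplanMeier:
    def test_all_events_hand_product_limit(self):
        curve = km_fit([1, 2, 3], [True, True, True])
        assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_censoring_removes_from_risk_set(self):
        # censored at 1, event at 2: S(1)=1 (no event), S(2)=1-1/1=0
        curve = km_fit([1, 2], [False, True])
        assert curve.survival_at(1) == pytest.approx(1.0)
        assert curve.survival_at(2) == pytest.approx(0.0)

    def test_no_events_survival_stays_one(self):
        curve = km_fit([3, 5, 8], [False, False, False])
        assert curve.survival_at(100) == 1.0

    def test_without_censoring_matches_empirical_fraction(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, size=50)
        curve = km_fit(times, np.ones(50, dtype=bool))
        for t in curve.times:
            assert curve.survival_at(t) == pytest.approx((times > t).mean())

    def test_monotone_within_unit_interval(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(10, size=80)
        events = rng.uniform(size=80) < 0.6
        curve = km_fit(times, events)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))

    def test_negative_time_is_fatal(self):
        with pytest.raises(ValueError):
            km_fit([-1, 2], [True, True])

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(2)
        times = rng.exponential(10, size=60)
        events = rng.uniform(size=60) < 0.7
        curve = km_fit(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t in curve.times:
            assert curve.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-9
            )


def two_group_data(seed=0, n=60, shift=0.6):
    rng = np.random.default_rng(seed)
    groups = rng.integers(0, 2, n)
    times = rng.exponential(10 * np.exp(-shift * groups))
    events = rng.uniform(size=n) < 0.7
    return times, events, groups


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [True, True, False, True]
        result = logrank(times + times, events + events, [0] * 4 + [1] * 4)
        assert result.chi_square == pytest.approx(0.0, abs=1e-9)
        assert result.p == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        times, events, groups = two_group_data()
        a = logrank(times, events, groups)
        b = logrank(times, events, 1 - groups)
        assert a.chi_square == pytest.approx(b.chi_square)

    def test_early_censored_sample_changes_nothing(self):
        times, events, groups = two_group_data()
        base = logrank(times, events, groups)
        t2 = np.append(times, times[events].min() / 2)
        e2 = np.append(events, False)
        g2 = np.append(groups, 1)
        assert logrank(t2, e2, g2).chi_square == pytest.approx(base.chi_square)

    def test_no_events_warns_and_p_is_one(self):
        with pytest.warns(UserWarning):
            result = logrank([1, 2, 3, 4], [False] * 4, [0, 0, 1, 1])
        assert result.p == 1.0

    def test_single_group_is_fatal(self):
        with pytest.raises(ValueError):
            logrank([1, 2], [True, True], [0, 0])

    @pytest.mark.parametrize("n_groups", [2, 3])
    def test_matches_lifelines(self, n_groups):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(5)
        n = 90
        groups = rng.integers(0, n_groups, n)
        times = rng.exponential(10 * np.exp(-0.5 * groups))
        events = rng.uniform(size=n) < 0.7
        mine = logrank(times, events, groups)
        theirs = multivariate_logrank_test(times, groups, events)
        assert mine.chi_square == pytest.approx(theirs.test_statistic, rel=1e-8)
        assert mine.p == pytest.approx(theirs.p_value, rel=1e-8)


class TestCox:
    def test_symmetric_duplication_gives_zero_effect(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, 40)
        events = rng.uniform(size=40) < 0.7
        # same data labelled 0 and 1: covariate carries no information
        t2 = np.concatenate([times, times])
        e2 = np.concatenate([events, events])
        x = np.concatenate([np.zeros(40), np.ones(40)])
        result = cox_fit(t2, e2, x, ties="breslow")
        assert abs(result.beta[0]) < 1e-6

    def test_centering_invariance(self):
        times, events, groups = two_group_data(seed=3)
        x = groups.astype(float)
        a = cox_fit(times, events, x)
        b = cox_fit(times, events, x + 100.0)
        assert a.beta[0] == pytest.approx(b.beta[0], abs=1e-8)

    def test_ci_contains_beta_and_matches_wald_width(self):
        times, events, groups = two_group_data(seed=4, n=120)
        result = cox_fit(times, events, groups.astype(float))
        assert result.ci_low[0] < result.beta[0] < result.ci_high[0]
        assert result.ci_high[0] - result.beta[0] == pytest.approx(1.96 * result.se[0])

    def test_efron_matches_lifelines_under_ties(self):
        from lifelines import CoxPHFitter
        import pandas as pd

        rng = np.random.default_rng(6)
        n = 120
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.normal(size=n)
        times = np.ceil(rng.exponential(5 * np.exp(-0.5 * x1)))  # heavy ties
        events = rng.uniform(size=n) < 0.8
        mine = cox_fit(times, events, np.column_stack([x1, x2]), ties="efron")
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": times, "e": events.astype(int), "x1": x1, "x2": x2}), "t", "e"
        )
        assert mine.beta == pytest.approx(cph.params_.values, abs=1e-5)
        assert mine.se == pytest.approx(cph.standard_errors_.values, abs=1e-5)

    def test_score_test_equals_logrank_without_ties(self):
        # with a binary covariate and untied times, the Cox score test at
        # beta=0 and the two-group log-rank statistic coincide
        times, events, groups = two_group_data(seed=7, n=80)
        assert len(np.unique(times)) == len(times)
        x = (groups.astype(float) - groups.mean())[:, None]
        _, grad, hess = _cox_derivatives(
            np.zeros(1), np.asarray(times), np.asarray(events, bool), x, "breslow"
        )
        score_stat = float(grad @ np.linalg.solve(-hess, grad))
        assert score_stat == pytest.approx(
            logrank(times, events, groups).chi_square, rel=1e-8
        )

    def test_loglik_non_decreasing_over_iterations(self):
        times, events, groups = two_group_data(seed=8, n=100)
        result = cox_fit(times, events, groups.astype(float))
        assert np.all(np.diff(result.loglik_path) >= -1e-9)

    def test_constant_covariate_is_fatal(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1, 2, 3], [True, True, True], np.ones(3))

    def test_complete_separation_is_flagged(self):
        # every x=1 subject fails before every x=0 subject: monotone likelihood
        times = np.array([1, 2, 3, 4, 5, 11, 12, 13, 14, 15], dtype=float)
        events = np.ones(10, dtype=bool)
        x = np.array([1] * 5 + [0] * 5, dtype=float)
        result = cox_fit(times, events, x)
        assert not result.converged
        assert np.isnan(result.beta).all()

    def test_recovers_true_effect_in_simulation(self):
        rng = np.random.default_rng(9)
        n = 800
        group = rng.integers(0, 2, n).astype(float)
        ggg = rng.integers(1, 6, n).astype(float)
        spec = SurvivalSimSpec(beta_burden=0.7, beta_ggg=0.6)
        times, events = simulate_survival(rng, group, ggg, spec)
        result = cox_fit(times, events, np.column_stack([group, ggg]))
        assert result.converged
        assert abs(result.beta[0] - 0.7) < 3 * result.se[0]
        assert abs(result.beta[1] - 0.6) < 3 * result.se[1]


class TestAssignGroups:
    def test_burden_median_rule_with_tie_to_high_group(self):
        table = BurdenTable({"S1": 1, "S2": 2, "S3": 3, "S4": 4}, 2.5, "all")
        groups = assign_groups(GroupingSpec("burden_median"), burdens=table)
        assert groups == {"S1": 0, "S2": 0, "S3": 1, "S4": 1}
        at_median = BurdenTable({"S1": 2, "S2": 2, "S3": 1}, 2.0, "all")
        assert assign_groups(GroupingSpec("burden_median"), burdens=at_median)["S1"] == 1

    def test_fusion_status_mode(self, make_call, make_cohort):
        cohort = make_cohort(
            [
                make_call(sample_id="S1", gene1="TMPRSS2", gene2="ERG", confidence="high"),
                make_call(sample_id="S2", gene1="A", gene2="B", confidence="high"),
            ]
        )
        spec = GroupingSpec("fusion_status", target_fusion="TMPRSS2::ERG")
        groups = assign_groups(spec, cohort_calls=cohort, samples=["S1", "S2", "S3"])
        assert groups == {"S1": 1, "S2": 0, "S3": 0}

    def test_single_group_warns(self):
        table = BurdenTable({"S1": 5, "S2": 5}, 5.0, "all")
        with pytest.warns(UserWarning):
            assign_groups(GroupingSpec("burden_median"), burdens=table)

    def test_fusion_status_requires_target(self):
        with pytest.raises(ValueError):
            GroupingSpec("fusion_status")
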