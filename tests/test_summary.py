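import itertools
import math

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from fusionburden.io import ClinicalRecord
from fusionburden.summary import (
    age_group_comparison,
    dedup_sample_fusions,
    per_sample_burden,
    rank_sum_test,
    summarize_cohort,
)


class TestDedup:
    def test_prefers_highest_confidence(self, make_call):
        kept = dedup_sample_fusions(
            [make_call(confidence="medium"), make_call(confidence="high")]
        )
        assert [c.confidence for c in kept] == ["high"]

    def test_breaks_ties_by_supporting_reads(self, make_call):
        kept = dedup_sample_fusions(
            [
                make_call(confidence="high", split_reads1=5, split_reads2=5, discordant_mates=0),
                make_call(confidence="high", split_reads1=10, split_reads2=10, discordant_mates=5),
            ]
        )
        assert [c.supporting_reads for c in kept] == [25]

    def test_full_tie_keeps_first(self, make_call):
        a = make_call(breakpoint1="1:100")
        b = make_call(breakpoint1="1:999")
        assert dedup_sample_fusions([a, b]) == [a]

    def test_single_call_unchanged(self, make_call):
        call = make_call()
        assert dedup_sample_fusions([call]) == [call]

    def test_multiple_samples_rejected(self, make_call):
        with pytest.raises(ValueError):
            dedup_sample_fusions([make_call(sample_id="S1"), make_call(sample_id="S2")])

    @settings(
        max_examples=100,
        deadline=None,
        suppress_health_check=[HealthCheck.function_scoped_fixture],  # pure factory
    )
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["A::B", "C::D", "E::F"]),
                st.sampled_from(["high", "medium", "low"]),
                st.integers(0, 30),
            ),
            max_size=12,
        )
    )
    def test_idempotent_and_never_grows(self, make_call, rows):
        calls = [
            make_call(gene1=key.split("::")[0], gene2=key.split("::")[1],
                      confidence=conf, split_reads1=reads)
            for key, conf, reads in rows
        ]
        once = dedup_sample_fusions(calls)
        assert len(once) <= len(calls)
        assert dedup_sample_fusions(once) == once
        assert len({c.key.key for c in once}) == len(once)


class TestSummarize:
    def test_two_sample_hand_enumeration(self, make_call, make_cohort):
        # S1={A::B high, C::D low}, S2={A::B high}
        cohort = make_cohort(
            [
                make_call(sample_id="S1", confidence="high"),
                make_call(sample_id="S1", gene1="C", gene2="D", confidence="low"),
                make_call(sample_id="S2", confidence="high"),
            ]
        )
        table = summarize_cohort(cohort)
        assert table.levels["all"].n_fusions == 3
        assert table.levels["high"].n_fusions == 2
        assert table.levels["high"].n_unique == 1
        assert table.levels["high"].mean_per_sample == 1.0

    def test_key_at_two_levels_counts_once_per_level(self, make_call, make_cohort):
        cohort = make_cohort(
            [make_call(confidence="high"), make_call(confidence="low")]
        )
        table = summarize_cohort(cohort)
        assert table.levels["all"].n_fusions == 1
        assert table.levels["high"].n_fusions == 1
        assert table.levels["low"].n_fusions == 1
        # per-level counts may exceed the all-confidence total
        assert (
            table.levels["high"].n_fusions + table.levels["low"].n_fusions
            > table.levels["all"].n_fusions
        )

    def test_mean_uses_all_samples_as_denominator(self, make_call, make_cohort):
        cohort = make_cohort([make_call(confidence="high")], n_samples=4)
        assert summarize_cohort(cohort).levels["high"].mean_per_sample == 0.25


class TestBurden:
    def test_median_is_midpoint_for_even_n(self, make_call, make_cohort):
        calls = [
            make_call(sample_id=f"S{i}", gene1=f"G{i}{j}", gene2="X")
            for i, n in enumerate([1, 2, 3, 4], start=1)
            for j in range(n)
        ]
        burdens = per_sample_burden(make_cohort(calls), "all")
        assert sorted(burdens.burdens.values()) == [1, 2, 3, 4]
        assert burdens.median_burden == 2.5

    def test_clinical_sample_without_calls_gets_zero(self, make_call, make_cohort):
        clinical = [
            ClinicalRecord("S1", "P1", 10.0, False),
            ClinicalRecord("S9", "P9", 20.0, True),
        ]
        burdens = per_sample_burden(make_cohort([make_call()]), "all", clinical)
        assert burdens.burdens["S9"] == 0

    def test_high_only_scope_excludes_lower_confidence(self, make_call, make_cohort):
        cohort = make_cohort(
            [
                make_call(confidence="high"),
                make_call(gene1="C", gene2="D", confidence="medium"),
                make_call(gene1="E", gene2="F", confidence="low"),
            ]
        )
        assert per_sample_burden(cohort, "high_only").burdens["S1"] == 1
        assert per_sample_burden(cohort, "all").burdens["S1"] == 3

    def test_combined_scope_counts_matched_keys(self, make_call, make_cohort):
        cohort = make_cohort(
            [make_call(confidence="low"), make_call(gene1="C", gene2="D", confidence="low")]
        )
        burdens = per_sample_burden(cohort, "combined", combined_keys={"A::B"})
        assert burdens.burdens["S1"] == 1


def mann_whitney_permutation_oracle(x, y, alternative="two-sided"):
    """Independent oracle: U statistic by pair counting, full enumeration."""

    def u_stat(a, b):
        return sum(
            1.0 if ai > bi else 0.5 if ai == bi else 0.0 for ai in a for bi in b
        )

    pooled = list(x) + list(y)
    nx = len(x)
    mu = len(x) * len(y) / 2
    u_obs = u_stat(x, y)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat([pooled[i] for i in idx], rest)
        if alternative == "two-sided":
            hits += abs(u - mu) >= abs(u_obs - mu) - 1e-9
        elif alternative == "less":
            hits += u <= u_obs + 1e-9
        total += 1
    return hits / total


class TestRankSum:
    def test_exact_small_example(self):
        _, p = rank_sum_test([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3, abs=1e-9)

    def test_identical_groups_give_p_one(self):
        _, p = rank_sum_test([5, 6, 7], [5, 6, 7])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_permutation_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(2, 9, size=2)
        x = rng.integers(0, 6, size=nx).tolist()  # ties likely
        y = rng.integers(0, 6, size=ny).tolist()
        for alternative in ("two-sided", "less"):
            _, p = rank_sum_test(x, y, alternative)
            oracle = mann_whitney_permutation_oracle(x, y, alternative)
            assert p == pytest.approx(oracle, abs=1e-3)

    def test_monotone_shift_never_raises_one_sided_p(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=6).tolist()
        y = rng.normal(size=6).tolist()
        _, p_before = rank_sum_test(x, y, "less")
        _, p_after = rank_sum_test(x, [v + 2.0 for v in y], "less")
        assert p_after <= p_before + 1e-12

    def test_large_sample_branch_tracks_scipy(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.8, 1, 40)
        _, p = rank_sum_test(x, y)
        assert 0 < p < 0.05  # clear shift detected through the asymptotic path


class TestAgeGroups:
    def make_inputs(self, make_call, make_cohort, ages, burdens):
        calls = [
            make_call(sample_id=f"S{i}", gene1=f"G{i}{j}", gene2="X")
            for i, n in enumerate(burdens, start=1)
            for j in range(n)
        ]
        cohort = make_cohort(calls, n_samples=len(ages))
        clinical = [
            ClinicalRecord(f"S{i}", f"P{i}", 10.0, False, specimen_age=a)
            for i, a in enumerate(ages, start=1)
        ]
        table = per_sample_burden(cohort, "all", clinical)
        return table, clinical

    def test_tertiles_tie_goes_to_younger_group(self, make_call, make_cohort):
        ages = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        table, clinical = self.make_inputs(make_call, make_cohort, ages, [5] * 9)
        result = age_group_comparison(table, clinical)
        groups = [result.groups[f"S{i}"] for i in range(1, 10)]
        # boundaries at the 1/3 and 2/3 empirical quantiles; equality -> younger
        assert groups == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_detects_burden_decline_with_age(self, make_call, make_cohort):
        ages = list(range(1, 13))
        burdens = [9, 9, 8, 8, 3, 2, 2, 1, 1, 0, 1, 0]
        table, clinical = self.make_inputs(make_call, make_cohort, ages, burdens)
        result = age_group_comparison(table, clinical)
        assert result.group_means[0] > result.group_means[-1]
        assert result.p_value < 0.05

    def test_missing_age_is_fatal_and_lists_samples(self, make_call, make_cohort):
        table, clinical = self.make_inputs(make_call, make_cohort, [1, 2, 3], [1, 1, 1])
        clinical[1].specimen_age = None
        with pytest.raises(ValueError, match="S2"):
            age_group_comparison(table, clinical)
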