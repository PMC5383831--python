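"""Per-individual sexing, cross-validation and the cohort statistics."""

import itertools

import numpy as np
import pytest

from radgsd import (
    FEMALE,
    MALE,
    UNKNOWN,
    PresenceMatrix,
    SampleTable,
    SexSpecificResult,
    assign_by_axis,
    assign_by_specific,
    crossvalidate,
    rank_sum_test,
    sex_ratio_test,
)
from radgsd.assignment import UNASSIGNED, sex_ratio_by_population


def make_table(sexes, pops=None) -> SampleTable:
    n = len(sexes)
    return SampleTable(
        [f"S{i}" for i in range(n)], pops or ["P0"] * n, list(sexes)
    )


class TestAssignByAxis:
    def test_side_of_midpoint_decides(self):
        coords = np.array([1.0, 1.0, -1.0, -1.0, 0.8, -0.9])
        table = make_table([MALE, MALE, FEMALE, FEMALE, UNKNOWN, UNKNOWN])
        calls, mid = assign_by_axis(coords, table)
        assert mid == pytest.approx(0.0)
        assert list(calls) == [MALE, MALE, FEMALE, FEMALE, MALE, FEMALE]

    def test_midpoint_falls_in_dead_zone(self):
        coords = np.array([1.0, 1.0, -1.0, -1.0, 0.0])
        table = make_table([MALE, MALE, FEMALE, FEMALE, UNKNOWN])
        calls, _ = assign_by_axis(coords, table)
        assert calls[4] == UNASSIGNED

    def test_equal_centroids_warns_and_unassigns(self):
        coords = np.zeros(4)
        table = make_table([MALE, MALE, FEMALE, FEMALE])
        with pytest.warns(UserWarning):
            calls, _ = assign_by_axis(coords, table)
        assert (calls == UNASSIGNED).all()


class TestAssignBySpecific:
    def _presence(self, rows):
        rows = np.asarray(rows, dtype=np.int64)
        return PresenceMatrix(
            samples=[f"S{i}" for i in range(rows.shape[0])],
            loci=[f"L{j}" for j in range(rows.shape[1])],
            counts=rows,
        )

    def test_extremes_called_and_middle_unassigned(self):
        specific = SexSpecificResult(["L0", "L1", "L2", "L3"], [], 3, 3)
        presence = self._presence(
            [[1, 1, 2, 5], [0, 0, 0, 0], [1, 0, 0, 0]]
        )
        calls, n_present, frac = assign_by_specific(presence, specific)
        assert list(calls) == [MALE, FEMALE, UNASSIGNED]
        assert list(n_present) == [4, 0, 1]
        assert frac[2] == pytest.approx(0.25)

    def test_female_specific_loci_swap_the_calls(self):
        specific = SexSpecificResult([], ["L0", "L1"], 3, 3)
        presence = self._presence([[1, 1], [0, 0]])
        calls, _, _ = assign_by_specific(presence, specific)
        assert list(calls) == [FEMALE, MALE]

    def test_empty_specific_set_raises(self):
        specific = SexSpecificResult([], [], 3, 3)
        with pytest.raises(ValueError):
            assign_by_specific(self._presence([[1]]), specific)


class TestCrossvalidate:
    def test_agreement_produces_no_flags(self):
        table = make_table([MALE, FEMALE, UNKNOWN])
        cv = crossvalidate([MALE, FEMALE, MALE], [MALE, FEMALE, MALE], table)
        assert cv.discordant_samples == []
        assert not cv.table["method_conflict"].any()
        assert list(cv.table["consensus_sex"]) == [MALE, FEMALE, MALE]

    def test_phenotyped_female_with_male_consensus_is_flagged(self):
        table = make_table([FEMALE, FEMALE])
        cv = crossvalidate([MALE, FEMALE], [MALE, FEMALE], table)
        assert cv.discordant_samples == ["S0"]

    def test_method_disagreement_unassigns_and_flags(self):
        table = make_table([UNKNOWN])
        cv = crossvalidate([MALE], [FEMALE], table)
        assert list(cv.table["consensus_sex"]) == [UNASSIGNED]
        assert cv.table["method_conflict"].all()
        assert cv.discordant_samples == []  # unphenotyped: never discordant

    def test_single_method_call_stands(self):
        table = make_table([UNKNOWN, UNKNOWN])
        cv = crossvalidate([MALE, UNASSIGNED], [UNASSIGNED, FEMALE], table)
        assert list(cv.table["consensus_sex"]) == [MALE, FEMALE]

    def test_consensus_never_contradicts_both_calls(self, rng):
        options = [MALE, FEMALE, UNASSIGNED]
        table = make_table([UNKNOWN] * 9 * 9)
        axis_calls, spec_calls = zip(
            *itertools.product(options, options, repeat=1)
        )  # 9 combos
        axis_calls = list(axis_calls) * 9
        spec_calls = list(spec_calls) * 9
        cv = crossvalidate(axis_calls[:81], spec_calls[:81], table)
        for a, s, c in zip(axis_calls, spec_calls, cv.table["consensus_sex"]):
            if c != UNASSIGNED:
                assert c in (a, s)


class TestSexRatioTest:
    def test_balanced_counts_give_p_one(self):
        assert sex_ratio_test(15, 15) == pytest.approx(1.0)

    def test_fully_skewed_closed_form(self):
        assert sex_ratio_test(30, 0) == pytest.approx(2 * 0.5**30)

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            sex_ratio_test(0, 0)

    def test_per_population_table(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "population": ["A"] * 4 + ["B"] * 2,
                "consensus_sex": [MALE, MALE, FEMALE, FEMALE, MALE, MALE],
            }
        )
        out = sex_ratio_by_population(table)
        assert list(out["population"]) == ["ALL", "A", "B"]
        assert out.loc[1, "p_value"] == pytest.approx(1.0)
        assert out.loc[2, "p_value"] == pytest.approx(0.5)


def exhaustive_rank_sum_p(a, b):
    """Two-sided WMW p by enumerating every assignment of the pooled values."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(group_a, group_b):
        return sum(x > y for x in group_a for y in group_b) + 0.5 * sum(
            x == y for x in group_a for y in group_b
        )

    mu = len(a) * len(b) / 2
    observed = abs(u_stat(a, b) - mu)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if abs(u_stat(ga, gb) - mu) >= observed - 1e-12:
            count += 1
    return count / total


class TestRankSumTest:
    def test_identical_groups_give_p_one(self):
        assert rank_sum_test([1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_exact_small_sample_matches_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        expected = exhaustive_rank_sum_p(a, b)
        assert expected == pytest.approx(0.1)
        assert rank_sum_test(a, b) == pytest.approx(expected)

    def test_enumeration_agreement_on_random_small_samples(self, rng):
        for _ in range(5):
            a = rng.permutation(20)[:4].astype(float)
            b = rng.permutation(40)[:5].astype(float) + 0.5
            assert rank_sum_test(a, b) == pytest.approx(
                exhaustive_rank_sum_p(list(a), list(b))
            )

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_null_type_one_error_near_nominal(self, rng):
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            a, b = rng.normal(size=30), rng.normal(size=30)
            if rank_sum_test(a, b) <= 0.05:
                rejections += 1
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) < 4 * se
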