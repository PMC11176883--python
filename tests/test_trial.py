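"""Group assignment, simulation harness, comparison stats, power calculation."""

import math

import numpy as np
import pytest

from mealcombo.profiles import UserProfile
from mealcombo.trial import (
    DegenerateDesignError,
    PowerParams,
    assign_groups,
    compare_outcomes,
    inflate_for_attrition,
    paired_t,
    required_sample_size,
    run_simulation,
    welch_t,
)


def user_with_history(uid, n):
    return UserProfile(
        id=uid, sex="male", age_years=70, weight_kg=65.0, bmi=23.0,
        income_band="low", activity_level="light",
        history=[(-(k + 1), ("d1",)) for k in range(n)],
    )


class TestGroups:
    def test_no_records_untracked(self):
        assignment = assign_groups([user_with_history("a", 0), user_with_history("b", 7)])
        assert assignment.untracked == {"a"} and assignment.tracked == {"b"}

    def test_exactly_five_records_is_tracked(self):
        assignment = assign_groups([user_with_history("a", 5)])
        assert assignment.tracked == {"a"}

    def test_default_cohort_split_34_62(self, default_cohort):
        assignment = assign_groups(default_cohort)
        assert len(assignment.tracked) == 34
        assert len(assignment.untracked) == 62


class TestPower:
    def test_reproduces_published_values(self):
        n = required_sample_size(PowerParams(delta=2.0, sigma=6.0, rho=0.5))
        assert n == 71
        assert inflate_for_attrition(n, 0.20) == 89

    def test_rho_zero_doubles_the_variance_term(self):
        assert required_sample_size(PowerParams(rho=0.0)) == 142

    def test_quarter_scaling_in_delta(self):
        assert required_sample_size(PowerParams(delta=4.0)) == 18

    def test_attrition_edge_cases(self):
        assert inflate_for_attrition(50, 0.0) == 50
        assert inflate_for_attrition(10, 0.5) == 20
        with pytest.raises(ValueError):
            inflate_for_attrition(10, 1.0)

    def test_degenerate_design(self):
        with pytest.raises(DegenerateDesignError):
            required_sample_size(PowerParams(rho=1.0))

    def test_monotonicities(self):
        base = required_sample_size(PowerParams())
        assert required_sample_size(PowerParams(delta=3.0)) <= base
        assert required_sample_size(PowerParams(rho=0.7)) <= base
        assert required_sample_size(PowerParams(sigma=8.0)) >= base
        assert required_sample_size(PowerParams(power=0.9)) >= base


class TestTTests:
    def test_paired_textbook_example(self):
        """Differences (1, 1, 2): mean 4/3, sd 1/sqrt(3), t = 4, df = 2."""
        t, df, p = paired_t(np.array([6.0, 7.0, 9.0]), np.array([5.0, 6.0, 7.0]))
        assert t == pytest.approx(4.0, abs=1e-12)
        assert df == 2

    def test_identical_vectors(self):
        t, _df, p = paired_t(np.array([5.0, 6.0, 7.0]), np.array([5.0, 6.0, 7.0]))
        assert t == 0.0 and p == 1.0

    def test_welch_fractional_df(self):
        """Welch-Satterthwaite df recomputed by hand from the variances."""
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 6.0, 10.0])
        t, df, _p = welch_t(a, b)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        expected_t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        expected_df = (va + vb) ** 2 / (
            va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
        )
        assert t == pytest.approx(expected_t, abs=1e-12)
        assert df == pytest.approx(expected_df, abs=1e-12)
        assert df != int(df)


class TestSimulation:
    def test_zero_days_empty(self, small_kg, small_cohort):
        result = run_simulation(small_cohort, small_kg, days=0, seed=3)
        assert result.records == []

    def test_structure_and_determinism(self, small_kg, small_cohort):
        cohort = [u for u in small_cohort if u.history_length() >= 5][:2]
        first = run_simulation(cohort, small_kg, days=3, n_options=3, seed=9)
        again = run_simulation(cohort, small_kg, days=3, n_options=3, seed=9)
        assert len(first.records) + len(first.skipped) == 6
        assert [r.to_dict() for r in first.records] == [r.to_dict() for r in again.records]
        for r in first.records:
            assert 0 <= r.selected < len(r.offered)
            assert len(r.offered) <= 3

    def test_day_one_offers_do_not_depend_on_seed(self, small_kg, small_cohort):
        cohort = [u for u in small_cohort if u.history_length() >= 5][:2]
        a = run_simulation(cohort, small_kg, days=1, seed=1)
        b = run_simulation(cohort, small_kg, days=1, seed=2)
        offers_a = {r.user_id: r.offered for r in a.records}
        offers_b = {r.user_id: r.offered for r in b.records}
        assert offers_a == offers_b

    def test_tracked_histories_grow_and_update_rankings(self, small_kg, small_cohort):
        cohort = [u for u in small_cohort if u.history_length() >= 5][:2]
        before = [len(u.history) for u in cohort]
        run_simulation(cohort, small_kg, days=3, seed=4)
        # input profiles untouched (the harness works on copies)
        assert [len(u.history) for u in cohort] == before

    def test_weekday_restriction(self, small_kg, small_cohort):
        cohort = [u for u in small_cohort if u.history_length() >= 5][:1]
        result = run_simulation(cohort, small_kg, days=30, seed=1, weekdays_only=True)
        days = {r.day for r in result.records} | {d for _u, d in result.skipped}
        assert len(days) == 22

    def test_jsonl_roundtrip(self, small_kg, small_cohort, tmp_path):
        cohort = [u for u in small_cohort if u.history_length() >= 5][:2]
        result = run_simulation(cohort, small_kg, days=2, seed=5)
        path = tmp_path / "sim.jsonl"
        result.to_jsonl(path)
        back = type(result).from_jsonl(path)
        assert [r.to_dict() for r in back.records] == [r.to_dict() for r in result.records]
        assert back.assignment.tracked == result.assignment.tracked


class TestComparison:
    def test_table_layout_and_columns(self, default_kg, default_cohort):
        result = run_simulation(default_cohort, default_kg, days=2, seed=3)
        table = compare_outcomes(result)
        assert list(table.columns) == [
            "group", "indicator", "autonomous_mean", "autonomous_sd",
            "recommended_mean", "recommended_sd", "t", "df", "p",
        ]
        assert len(table) == 4  # 2 groups x 2 indicators
        tracked = table[table.group == "tracked"]
        assert (tracked.df == len(result.assignment.tracked) - 1).all()

    def test_untracked_compared_against_tracked_autonomous(
        self, default_kg, default_cohort
    ):
        result = run_simulation(default_cohort, default_kg, days=2, seed=3)
        table = compare_outcomes(result)
        tracked = table[table.group == "tracked"].set_index("indicator")
        untracked = table[table.group == "untracked"].set_index("indicator")
        for indicator in ("dds", "quality"):
            assert untracked.loc[indicator, "autonomous_mean"] == pytest.approx(
                tracked.loc[indicator, "autonomous_mean"]
            )
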