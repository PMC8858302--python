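"""Costing: annuitization oracle, shadow-wage valuation, ledger aggregation."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pydantic import ValidationError

from nutribca import (
    CostItem,
    aggregate_costs,
    annuitized_capital_cost,
    opportunity_cost_value,
    read_ledger,
    write_ledger,
)


def pv_of_annuity(payment, life, rate):
    """Independent brute-force oracle: discounted sum of equal payments."""
    return sum(payment / (1 + rate) ** t for t in range(1, int(life) + 1))


class TestAnnuitization:
    # expected values frozen from the brute-force oracle above
    @pytest.mark.parametrize(
        "cost,life,rate,expected",
        [(100, 1, 0.03, 103.00), (1000, 10, 0.03, 117.23), (500, 5, 0.03, 109.18)],
    )
    def test_examples(self, cost, life, rate, expected):
        a = annuitized_capital_cost(cost, life, rate)
        assert a == pytest.approx(expected, abs=0.005)
        assert pv_of_annuity(a, life, rate) == pytest.approx(cost, rel=1e-12)

    def test_zero_rate_is_straight_line(self):
        assert annuitized_capital_cost(1000, 10, 0.0) == pytest.approx(100.0)

    def test_near_zero_rate_limit(self):
        assert annuitized_capital_cost(1000, 10, 1e-9) == pytest.approx(100.0, rel=1e-6)

    def test_negative_inputs_rejected(self):
        for bad in [(-1, 10, 0.03), (100, 0.5, 0.03), (100, 10, -0.01)]:
            with pytest.raises(ValueError):
                annuitized_capital_cost(*bad)

    @settings(max_examples=100, derandomize=True)
    @given(
        cost=st.floats(0.01, 1e7),
        life=st.integers(1, 50),
        rate=st.floats(1e-6, 0.5),
    )
    def test_oracle_equivalence(self, cost, life, rate):
        a = annuitized_capital_cost(cost, life, rate)
        assert pv_of_annuity(a, life, rate) == pytest.approx(cost, rel=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(life=st.integers(2, 40), rate=st.floats(0.001, 0.3))
    def test_monotone_in_rate_and_life(self, life, rate):
        a = annuitized_capital_cost(1000, life, rate)
        assert annuitized_capital_cost(1000, life, rate + 0.01) > a
        assert annuitized_capital_cost(1000, life + 1, rate) < a


class TestOpportunityCost:
    @pytest.mark.parametrize(
        "hours,wage,share,hpm,expected",
        [(176, 23, 0.5, 176, 11.50), (0, 23, 0.5, 176, 0.0), (352, 23, 1.0, 176, 46.00)],
    )
    def test_examples(self, hours, wage, share, hpm, expected):
        assert opportunity_cost_value(hours, wage, share, hpm) == pytest.approx(expected)

    def test_zero_hours_per_month_rejected(self):
        with pytest.raises(ValueError):
            opportunity_cost_value(10, 23, 0.5, 0)


def _ledger_hitting_targets(base):
    """Hand-built ledger whose valued items sum to the published totals."""
    capital_purchase = 10_000.0
    capital_value = annuitized_capital_cost(capital_purchase, 10, base.capital_discount_rate)
    hours = 3_000.0
    time_value = opportunity_cost_value(
        hours, base.monthly_min_wage, base.shadow_wage_share, base.hours_per_month
    )
    return [
        CostItem(
            label="preschool equipment", activity="start-up", input_category="capital",
            payer="program", amount=capital_purchase, useful_life_y=10,
        ),
        CostItem(
            label="salaries", activity="recurrent", input_category="personnel",
            payer="program", amount=147_916.0 - capital_value,
        ),
        CostItem(
            label="meal preparation", activity="recurrent", input_category="beneficiary time",
            payer="community", hours=hours,
        ),
        CostItem(
            label="food donations", activity="recurrent", input_category="food",
            payer="community", amount=49_461.0 - time_value,
        ),
    ]


class TestAggregate:
    def test_published_totals(self, base):
        s = aggregate_costs(_ledger_hitting_targets(base), base)
        assert s.program_total == pytest.approx(147_916, rel=1e-9)
        assert s.community_total == pytest.approx(49_461, rel=1e-9)
        assert s.grand_total == pytest.approx(197_377, rel=1e-9)

    def test_cost_efficiency_ratios(self, base):
        s = aggregate_costs(_ledger_hitting_targets(base), base)
        assert round(s.per_child) == 194
        assert round(s.per_household) == 219
        assert round(s.per_beneficiary) == 41

    def test_breakdowns_sum_to_grand_total(self, base):
        s = aggregate_costs(_ledger_hitting_targets(base), base)
        assert sum(s.by_activity.values()) == pytest.approx(s.grand_total, rel=1e-6)
        assert sum(s.by_input.values()) == pytest.approx(s.grand_total, rel=1e-6)

    def test_single_item_unit_counts(self, base):
        p = base.model_copy(update={"n_children": 1, "n_households": 1, "n_beneficiaries": 1})
        item = CostItem(label="x", activity="recurrent", input_category="other",
                        payer="program", amount=100.0)
        s = aggregate_costs([item], p)
        assert s.per_child == s.per_household == s.per_beneficiary == 100.0

    def test_permutation_invariance(self, base):
        ledger = _ledger_hitting_targets(base)
        shuffled = ledger[::-1]
        a, b = aggregate_costs(ledger, base), aggregate_costs(shuffled, base)
        assert a.grand_total == pytest.approx(b.grand_total, rel=1e-12)
        assert a.by_input == b.by_input

    def test_empty_ledger_rejected(self, base):
        with pytest.raises(ValueError):
            aggregate_costs([], base)

    def test_invalid_item_names_it(self):
        with pytest.raises(ValidationError, match="both"):
            CostItem(label="both", activity="recurrent", input_category="other",
                     payer="program", amount=1.0, hours=1.0)
        with pytest.raises(ValidationError, match="useful_life_y"):
            CostItem(label="cap", activity="start-up", input_category="capital",
                     payer="program", amount=1.0, useful_life_y=0.5)


class TestLedgerCSV:
    def test_round_trip(self, tmp_path, base):
        ledger = _ledger_hitting_targets(base)
        path = tmp_path / "ledger.csv"
        write_ledger(ledger, path)
        back = read_ledger(path)
        assert back == ledger

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("label,activity\nx,recurrent\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_ledger(path)
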