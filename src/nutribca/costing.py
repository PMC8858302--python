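"""Economic costing: ledgers, annuitization, opportunity cost, cost-efficiency.

The intervention is costed from a societal perspective over a 12-month
horizon. Itemized costs are coded by activity (start-up vs recurrent), input
category and payer (program vs community). Capital items enter at their
annuitized annual value; unpaid beneficiary labor enters at a shadow wage
(a configurable share of the monthly minimum wage, converted to an hourly
rate); everything else enters at face value. Cost-efficiency ratios divide
the grand total by the numbers of children, households and beneficiaries
reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .discounting import annuity_factor
from .params import ParameterSet, paper_base_case

__all__ = [
    "CostItem",
    "CostSummary",
    "annuitized_capital_cost",
    "opportunity_cost_value",
    "aggregate_costs",
    "read_ledger",
    "write_ledger",
]

Activity = Literal["start-up", "recurrent"]
InputCategory = Literal[
    "personnel",
    "agricultural inputs",
    "food",
    "consumables",
    "capital",
    "training",
    "transport",
    "beneficiary time",
    "other",
]
Payer = Literal["program", "community"]


class CostItem(BaseModel):
    """One ledger line: either a monetary amount or a block of volunteer hours."""

    label: str
    activity: Activity
    input_category: InputCategory
    payer: Payer
    amount: Optional[float] = Field(default=None, ge=0)
    hours: Optional[float] = Field(default=None, ge=0)
    useful_life_y: Optional[float] = None

    @model_validator(mode="after")
    def _exactly_one(self) -> "CostItem":
        if (self.amount is None) == (self.hours is None):
            raise ValueError(
                f"item {self.label!r}: exactly one of amount/hours must be set"
            )
        if self.input_category == "capital":
            if self.amount is None:
                raise ValueError(f"capital item {self.label!r} must carry an amount")
            if self.useful_life_y is None or self.useful_life_y < 1:
                raise ValueError(
                    f"capital item {self.label!r} needs useful_life_y >= 1"
                )
        return self


def annuitized_capital_cost(cost: float, useful_life_y: float, rate: float = 0.03) -> float:
    """Equivalent annual cost of a capital purchase over its useful life.

    Solves ``sum_{t=1..L} A / (1+r)^t = cost`` for A, i.e.
    ``A = cost * r / (1 - (1+r)^-L)``; at ``r = 0`` this is straight-line
    ``cost / L``.
    """
    if cost < 0 or useful_life_y < 1 or rate < 0:
        raise ValueError("require cost >= 0, useful_life_y >= 1, rate >= 0")
    return cost / annuity_factor(rate, useful_life_y)


def opportunity_cost_value(
    hours: float,
    monthly_min_wage: float = 23.0,
    shadow_share: float = 0.5,
    hours_per_month: float = 176.0,
) -> float:
    """Shadow-wage value of unpaid labor time.

    Volunteer time is valued at ``shadow_share`` of the monthly minimum wage
    (USD 23 for an unskilled apprentice in 2016 Malawi), converted to an
    hourly rate over ``hours_per_month`` working hours.
    """
    if min(hours, monthly_min_wage, shadow_share) < 0:
        raise ValueError("inputs must be >= 0")
    if hours_per_month <= 0:
        raise ValueError("hours_per_month must be > 0")
    return hours * shadow_share * monthly_min_wage / hours_per_month


def valued_amount(item: CostItem, params: ParameterSet) -> float:
    """Economic value of one ledger item under the costing conventions."""
    if item.hours is not None:
        return opportunity_cost_value(
            item.hours,
            params.monthly_min_wage,
            params.shadow_wage_share,
            params.hours_per_month,
        )
    if item.input_category == "capital":
        return annuitized_capital_cost(
            item.amount, item.useful_life_y, params.capital_discount_rate
        )
    return item.amount


@dataclass
class CostSummary:
    """Aggregated economic costs with category breakdowns and unit ratios."""

    program_total: float
    community_total: float
    grand_total: float
    by_activity: dict[str, float]
    by_input: dict[str, float]
    per_child: float
    per_household: float
    per_beneficiary: float

    def table(self) -> pd.DataFrame:
        """Display table with unit ratios rounded to the nearest dollar."""
        rows = [
            ("program cost (USD)", round(self.program_total)),
            ("community contribution (USD)", round(self.community_total)),
            ("total cost (USD)", round(self.grand_total)),
            ("cost per child (USD)", round(self.per_child)),
            ("cost per household (USD)", round(self.per_household)),
            ("cost per beneficiary (USD)", round(self.per_beneficiary)),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"]).set_index("quantity")


def aggregate_costs(
    ledger: Sequence[CostItem | dict], params: ParameterSet | None = None
) -> CostSummary:
    """Aggregate a ledger into economic cost totals and cost-efficiency ratios."""
    if params is None:
        params = paper_base_case()
    if len(ledger) == 0:
        raise ValueError("ledger is empty")
    items = [it if isinstance(it, CostItem) else CostItem.model_validate(it) for it in ledger]

    by_payer = {"program": 0.0, "community": 0.0}
    by_activity: dict[str, float] = {}
    by_input: dict[str, float] = {}
    for it in items:
        v = valued_amount(it, params)
        by_payer[it.payer] += v
        by_activity[it.activity] = by_activity.get(it.activity, 0.0) + v
        by_input[it.input_category] = by_input.get(it.input_category, 0.0) + v
    grand = by_payer["program"] + by_payer["community"]
    return CostSummary(
        program_total=by_payer["program"],
        community_total=by_payer["community"],
        grand_total=grand,
        by_activity=by_activity,
        by_input=by_input,
        per_child=grand / params.n_children,
        per_household=grand / params.n_households,
        per_beneficiary=grand / params.n_beneficiaries,
    )


_LEDGER_COLS = ["label", "activity", "input_category", "payer", "amount", "hours", "useful_life_y"]


def read_ledger(path: str | Path) -> list[CostItem]:
    """Read a UTF-8 CSV ledger (header row required; empty cells where inapplicable)."""
    df = pd.read_csv(path)
    missing = set(_LEDGER_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"ledger CSV missing columns: {sorted(missing)}")
    items = []
    for rec in df[_LEDGER_COLS].to_dict("records"):
        clean = {k: (None if pd.isna(v) else v) for k, v in rec.items()}
        items.append(CostItem.model_validate(clean))
    return items


def write_ledger(items: Iterable[CostItem], path: str | Path) -> None:
    df = pd.DataFrame([it.model_dump() for it in items], columns=_LEDGER_COLS)
    df.to_csv(path, index=False)
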