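"""End-to-end evaluation pipeline and its results container.

:class:`EconomicEvaluation` wires the stages together: cost aggregation
(optionally from an itemized ledger), effect estimation and ICERs, the VSL
comparison table, the three benefit streams and BCA summaries per discount
rate, and — on request — the Monte Carlo PSA and one-way tornado.
:class:`EvaluationResults` holds everything, renders a text summary and
serializes to the run-report JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .costing import CostItem, CostSummary, aggregate_costs
from .effects import EffectEstimates, effect_summary, icer
from .params import ParameterSet, paper_base_case
from .uncertainty import PSAResult, TornadoResult, one_way_tornado, run_psa
from .valuation import BCAResult, bca_summary, bca_table, vsl_table

__all__ = ["EconomicEvaluation", "EvaluationResults"]


@dataclass
class EvaluationResults:
    params: ParameterSet
    costs: CostSummary
    effects_standard: EffectEstimates
    effects_malawi: EffectEstimates
    icers: dict[str, float]
    vsl: pd.DataFrame
    bca: dict[float, BCAResult]
    psa: Optional[PSAResult] = None
    tornado: Optional[TornadoResult] = None

    def bca_frame(self) -> pd.DataFrame:
        return bca_table(self.params, list(self.bca))

    def summary(self) -> str:
        """Human-readable report (dollars rounded, BCR to 2 decimals)."""
        p = self.params
        lines = []
        lines.append("Economic evaluation summary (2016 USD)")
        lines.append("=" * 46)
        lines.append("Costs and cost-efficiency")
        lines.append(self.costs.table().to_string())
        lines.append("")
        lines.append("Cost-effectiveness")
        eff = self.effects_standard
        lines.append(f"  stunting cases averted : {p.stunting_cases_averted:.0f}")
        lines.append(f"  deaths averted         : {p.deaths_averted_display:d}")
        lines.append(f"  DALYs averted (standard LE): {eff.dalys:.1f}")
        lines.append(f"  DALYs averted (Malawi LE)  : {self.effects_malawi.dalys:.1f}")
        for k, v in self.icers.items():
            lines.append(f"  cost per {k}: ${round(v):,}")
        lines.append("")
        lines.append("VSL benefit transfer (Malawi)")
        lines.append(self.vsl.round(0).to_string())
        lines.append("")
        lines.append("Benefit-cost analysis (US-VSL extrapolation)")
        frame = self.bca_frame().round({"bcr": 2}).round(
            {c: 0 for c in ("mortality", "productivity", "agriculture", "total_benefit", "net_benefit")}
        )
        lines.append(frame.to_string())
        if self.psa is not None:
            lines.append("")
            lines.append("Probabilistic sensitivity analysis")
            lines.append(self.psa.summary().round(4).to_string())
        if self.tornado is not None:
            lines.append("")
            lines.append("One-way sensitivity (BCR swings, largest first)")
            lines.append(self.tornado.table.round(4).to_string(index=False))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "params": self.params.to_dict(),
            "costs": {
                "program_total": self.costs.program_total,
                "community_total": self.costs.community_total,
                "grand_total": self.costs.grand_total,
                "by_activity": self.costs.by_activity,
                "by_input": self.costs.by_input,
                "per_child": self.costs.per_child,
                "per_household": self.costs.per_household,
                "per_beneficiary": self.costs.per_beneficiary,
            },
            "effects": {
                "stunting_cases_averted": self.params.stunting_cases_averted,
                "deaths_averted": self.params.deaths_averted_unrounded,
                "dalys_standard": self.effects_standard.dalys,
                "dalys_malawi": self.effects_malawi.dalys,
                "icers": self.icers,
            },
            "vsl": self.vsl.reset_index().to_dict("records"),
            "bca": {
                str(rate): {
                    "mortality": r.streams.mortality,
                    "productivity": r.streams.productivity,
                    "agriculture": r.streams.agriculture,
                    "total_benefit": r.total_benefit,
                    "net_benefit": r.net_benefit,
                    "bcr": r.bcr,
                }
                for rate, r in self.bca.items()
            },
        }
        if self.psa is not None:
            d["psa"] = self.psa.to_dict()
        if self.tornado is not None:
            d["tornado"] = {
                "base_bcr": self.tornado.base_bcr,
                "table": self.tornado.table.to_dict("records"),
            }
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


class EconomicEvaluation:
    """The full evaluation, configured by a :class:`ParameterSet`.

    Parameters
    ----------
    params : ParameterSet, optional
        Assumptions; defaults to the packaged base case.
    ledger : sequence of CostItem, optional
        Itemized cost ledger. When omitted, cost totals come from the
        parameter registry (program/community/total).
    """

    def __init__(self, params: ParameterSet | None = None, ledger: Sequence[CostItem] | None = None):
        self.params = params if params is not None else paper_base_case()
        self.ledger = list(ledger) if ledger is not None else None

    def _cost_summary(self) -> CostSummary:
        p = self.params
        if self.ledger is not None:
            return aggregate_costs(self.ledger, p)
        return CostSummary(
            program_total=p.program_cost,
            community_total=p.community_cost,
            grand_total=p.total_cost,
            by_activity={},
            by_input={},
            per_child=p.total_cost / p.n_children,
            per_household=p.total_cost / p.n_households,
            per_beneficiary=p.total_cost / p.n_beneficiaries,
        )

    def run(
        self,
        rates: Sequence[float] | None = None,
        psa_draws: int | None = None,
        seed: int | None = None,
        tornado: bool = False,
    ) -> EvaluationResults:
        p = self.params
        if rates is None:
            rates = p.discount_rates
        costs = self._cost_summary()
        eff_std = effect_summary(p, "standard")
        eff_mwi = effect_summary(p, "malawi")
        total = costs.grand_total
        icers = {
            "stunting case averted": icer(total, p.stunting_cases_averted),
            "death averted": icer(total, p.deaths_averted_unrounded),
            "DALY averted (standard LE)": icer(total, eff_std.dalys),
            "DALY averted (Malawi LE)": icer(total, eff_mwi.dalys),
            "beneficiary": icer(total, p.n_beneficiaries),
        }
        bca = {d: bca_summary(p, d) for d in rates}
        psa = run_psa(p, n_draws=psa_draws, seed=seed) if psa_draws else None
        torn = one_way_tornado(p) if tornado else None
        return EvaluationResults(
            params=p,
            costs=costs,
            effects_standard=eff_std,
            effects_malawi=eff_mwi,
            icers=icers,
            vsl=vsl_table(p),
            bca=bca,
            psa=psa,
            tornado=torn,
        )
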