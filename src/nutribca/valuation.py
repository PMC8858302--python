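"""Benefit valuation: VSL transfer, three benefit streams, net benefit and BCR.

Three monetized benefit streams are valued in 2016 USD at each discount rate:

* **Mortality** — deaths averted times a Malawi VSL obtained by benefit
  transfer. The base case extrapolates the 2016 US VSL ($9.4m) with an
  income elasticity of 1.5 on the GNI-per-capita (PPP) ratio, then converts
  international dollars to market USD with the PPP price-level ratio
  (0.257). The stream is valued at the time of aversion, so it is identical
  across discount rates. Three alternative transfers (constant VSLY, 160x
  and 100x GNI per capita) are available for the comparison table.
* **Lifetime productivity** — each surviving averted case earns a wage
  premium (base 30%) over the stunted wage from age 16 to 60, with wages
  growing at the projected GNI-per-capita growth rate (4.46%/yr) and
  discounted back to 2016. The prevailing average wage ($750) mixes stunted
  and non-stunted earners, so the stunted wage is
  ``avg_wage / (1 + premium * (1 - prevalence))``.
* **Agriculture** — supplemental household production worth a calibrated
  annual base value over 20 years; the half sold at market appreciates with
  GNI growth while the consumed half stays at constant 2016 prices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import pandas as pd

from .discounting import growth_discount_sum
from .params import ParameterSet, paper_base_case

__all__ = [
    "VSLEstimate",
    "BenefitStreams",
    "BCAResult",
    "VSL_METHODS",
    "vsl_transfer",
    "vsl_table",
    "mortality_benefit",
    "productivity_benefit",
    "ag_base_value",
    "calibrate_ag_base",
    "agriculture_benefit",
    "bca_summary",
    "bca_table",
]

VSL_METHODS = ("us_extrapolation", "vsly", "us_ratio", "oecd_ratio")

#: GNI-per-capita multiples for the ratio-based VSL transfers.
US_RATIO_MULTIPLE = 160.0
OECD_RATIO_MULTIPLE = 100.0


@dataclass
class VSLEstimate:
    """A Malawi VSL in 2016 international dollars and market-exchange USD."""

    method: str
    value_intl: float
    value_usd: float


def vsl_transfer(method: str, params: ParameterSet | None = None) -> VSLEstimate:
    """Transfer a VSL to Malawi by one of four population-average methods.

    ``us_extrapolation``: ``VSL_US * (GNI_mwi / GNI_us)**elasticity``;
    ``vsly``: the extrapolated VSL spread over the undiscounted adult life
    expectancy (33.8 y) times the YLLs from death at age 2 (63.3 y);
    ``us_ratio`` / ``oecd_ratio``: 160x / 100x GNI per capita (PPP).
    USD values apply the PPP price-level ratio.
    """
    if params is None:
        params = paper_base_case()
    if method == "us_extrapolation":
        intl = params.vsl_us * (params.gni_pc_ppp_mwi / params.gni_pc_ppp_us) ** params.income_elasticity
    elif method == "vsly":
        base = params.vsl_us * (params.gni_pc_ppp_mwi / params.gni_pc_ppp_us) ** params.income_elasticity
        intl = base / params.adult_le_undiscounted * params.ylls_at_death_age
    elif method == "us_ratio":
        intl = US_RATIO_MULTIPLE * params.gni_pc_ppp_mwi
    elif method == "oecd_ratio":
        intl = OECD_RATIO_MULTIPLE * params.gni_pc_ppp_mwi
    else:
        raise ValueError(f"unknown VSL method {method!r}; expected one of {VSL_METHODS}")
    return VSLEstimate(method=method, value_intl=intl, value_usd=intl * params.ppp_price_ratio)


def vsl_table(params: ParameterSet | None = None) -> pd.DataFrame:
    """All four VSL transfers, in international dollars and USD."""
    ests = [vsl_transfer(m, params) for m in VSL_METHODS]
    return pd.DataFrame(
        {
            "method": [e.method for e in ests],
            "vsl_intl_2016": [e.value_intl for e in ests],
            "vsl_usd_2016": [e.value_usd for e in ests],
        }
    ).set_index("method")


def mortality_benefit(deaths_unrounded: float, vsl_usd: float) -> float:
    """Value of averted premature deaths; constant across discount rates."""
    if deaths_unrounded < 0 or vsl_usd < 0:
        raise ValueError("inputs must be >= 0")
    return deaths_unrounded * vsl_usd


def stunted_wage(params: ParameterSet) -> float:
    """Average wage of a stunted earner implied by the economy-wide wage.

    The observed average wage mixes non-stunted earners (share
    ``1 - prevalence``) paid a premium over stunted earners, so
    ``w_s = avg_wage / (1 + premium * (1 - prevalence))``.
    """
    return params.avg_wage / (1.0 + params.wage_premium * (1.0 - params.stunting_prevalence))


def productivity_benefit(params: ParameterSet | None = None, d: float = 0.10) -> float:
    """Present value of lifetime wage gains for surviving averted cases.

    Children averted from stunting (net of deaths averted, to avoid double
    counting with the mortality stream) earn an extra
    ``premium * stunted_wage`` each year from age 16 to 60; wages grow with
    GNI per capita and are discounted at ``d``. For a child aged 2 in 2016
    that is years 14..58 after 2016 (45 working years).
    """
    if params is None:
        params = paper_base_case()
    if d < 0:
        raise ValueError("discount rate must be >= 0")
    n = params.stunting_cases_averted - params.deaths_averted_unrounded
    annual_gain = params.wage_premium * stunted_wage(params)
    t_start = params.work_start_age - params.child_age_2016
    t_end = params.work_end_age - params.child_age_2016
    factor = growth_discount_sum(params.gni_growth, d, t_start, t_end, grow_share=1.0)
    return n * annual_gain * factor


def ag_base_value(
    quantities: Mapping[str, float],
    prices: Mapping[str, float],
    n_households: int,
) -> float:
    """Annual value of supplemental production from per-household quantities.

    ``quantities`` maps crop/product to kg (or head/eggs) per household per
    year; ``prices`` maps the same keys to 2016 USD per unit.
    """
    missing = set(quantities) - set(prices)
    if missing:
        raise ValueError(f"no price for: {sorted(missing)}")
    if any(v < 0 for v in quantities.values()) or any(v < 0 for v in prices.values()):
        raise ValueError("quantities and prices must be >= 0")
    return n_households * sum(q * prices[k] for k, q in quantities.items())


def calibrate_ag_base(
    target_pv: float,
    params: ParameterSet | None = None,
    d: float = 0.03,
) -> float:
    """Annual base value whose discounted mixed-growth stream has PV ``target_pv``."""
    if params is None:
        params = paper_base_case()
    if target_pv < 0:
        raise ValueError("target_pv must be >= 0")
    factor = growth_discount_sum(params.gni_growth, d, 1, params.ag_years, params.share_sold)
    if factor == 0:
        raise ValueError("degenerate zero discount factor")
    return target_pv / factor


def agriculture_benefit(params: ParameterSet | None = None, d: float = 0.10) -> float:
    """Present value of supplemental household agricultural production.

    The annual base value runs for ``ag_years`` years; the sold share
    appreciates with GNI growth while the consumed share is valued at
    constant 2016 prices, both discounted at ``d``.
    """
    if params is None:
        params = paper_base_case()
    if d < 0:
        raise ValueError("discount rate must be >= 0")
    factor = growth_discount_sum(params.gni_growth, d, 1, params.ag_years, params.share_sold)
    return params.ag_base_annual_value * factor


@dataclass
class BenefitStreams:
    """The three valued benefit streams at one discount rate (2016 USD)."""

    discount_rate: float
    mortality: float
    productivity: float
    agriculture: float

    @property
    def total(self) -> float:
        return self.mortality + self.productivity + self.agriculture


@dataclass
class BCAResult:
    """Benefit-cost summary at one discount rate."""

    streams: BenefitStreams
    total_cost: float

    @property
    def total_benefit(self) -> float:
        return self.streams.total

    @property
    def net_benefit(self) -> float:
        return self.streams.total - self.total_cost

    @property
    def bcr(self) -> float:
        return self.streams.total / self.total_cost


def bca_summary(params: ParameterSet | None = None, d: float | None = None) -> BCAResult:
    """Assemble the three streams, net benefit and BCR at discount rate ``d``."""
    if params is None:
        params = paper_base_case()
    if d is None:
        d = params.base_case_rate
    if params.total_cost <= 0:
        raise ValueError("total_cost must be > 0")
    vsl = vsl_transfer("us_extrapolation", params)
    streams = BenefitStreams(
        discount_rate=d,
        mortality=mortality_benefit(params.deaths_averted_unrounded, vsl.value_usd),
        productivity=productivity_benefit(params, d),
        agriculture=agriculture_benefit(params, d),
    )
    return BCAResult(streams=streams, total_cost=params.total_cost)


def bca_table(params: ParameterSet | None = None, rates=None) -> pd.DataFrame:
    """Streams, totals, net benefits and BCRs across discount rates."""
    if params is None:
        params = paper_base_case()
    if rates is None:
        rates = params.discount_rates
    rows = []
    for d in rates:
        r = bca_summary(params, d)
        rows.append(
            {
                "discount_rate": d,
                "mortality": r.streams.mortality,
                "productivity": r.streams.productivity,
                "agriculture": r.streams.agriculture,
                "total_benefit": r.total_benefit,
                "net_benefit": r.net_benefit,
                "bcr": r.bcr,
            }
        )
    return pd.DataFrame(rows).set_index("discount_rate")
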